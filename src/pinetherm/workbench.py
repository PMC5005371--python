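"""I/O, configuration, and the end-to-end pipeline.

The pipeline chains: simulate (experiment table + demo thermal scenes) ->
process-images (segmentation, median temperatures) -> compute-indices ->
fit models (treatment stress/recovery and/or soil-water-deficit family) ->
report.  Every stage writes plain-text artifacts (CSV/JSON) into the
output directory and a manifest records the seed, a config hash and
per-file content hashes, so identical (config, seed) runs are verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TIME_SCALE_DAYS
from .imaging import SegmentationConfig, ThermalImage, segment_scene
from .indices import cwsi as _cwsi, ig as _ig, vpd as _vpd
from .lmm import fit_lmm, r2_glmm
from .stress_models import (
    build_pswd_model,
    provenance_contrasts,
    select_meteo_covariates,
    simplify_model,
)
from .synthetic import (
    ExperimentParams,
    SceneParams,
    default_region_layout,
    generate_experiment,
    generate_thermal_scene,
)
from .treatment_models import (
    RECOVERY_WINDOW,
    STRESS_WINDOW,
    build_treatment_model,
    response_magnitude,
    treatment_contrasts,
    treatment_effect_reduction,
)

logger = logging.getLogger("pinetherm")

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_config",
    "run_pipeline",
    "read_observations",
    "write_observations",
    "OBSERVATION_COLUMNS",
]

#: column dictionary of the observation table (units in the description)
OBSERVATION_COLUMNS: Mapping[str, str] = {
    "tree_id": "tree identifier (string)",
    "provenance": "seed-origin label, e.g. ES1",
    "treatment": "'control' or 'drought'",
    "day": "measuring-day index 1..17",
    "day_offset": "days since the study start",
    "order_in_day": "within-day measurement order (optional)",
    "t_canopy": "canopy median temperature, degC (optional)",
    "t_wet": "wet-reference median temperature, degC (optional)",
    "t_dry": "dry-reference median temperature, degC (optional)",
    "height": "seedling height, mm",
    "diameter": "stem diameter, mm",
    "air_temp": "air temperature, degC",
    "rh": "relative humidity, %",
    "radiation": "solar radiation, W/m^2",
    "vpd": "vapor pressure deficit, kPa",
    "pswd": "percent soil water deficit, deficit-positive fraction",
    "cwsi": "crop water stress index (dimensionless)",
    "ig": "stomatal conductance index (dimensionless)",
}

_REQUIRED = ("tree_id", "provenance", "treatment", "day")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation CSV (UTF-8, '.' decimal)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"observation file missing required column(s): {missing}")
    unknown = [c for c in df.columns if c not in OBSERVATION_COLUMNS]
    if unknown:
        warnings.warn(f"unknown observation column(s) ignored by models: {unknown}",
                      stacklevel=2)
    if "rh" in df.columns:
        bad = df.index[(df["rh"] <= 0) | (df["rh"] > 100)].tolist()
        if bad:
            raise ValueError(f"relative humidity outside (0, 100] in row(s) {bad[:10]}")
    if "air_temp" in df.columns and (df["air_temp"] <= -40).any():
        bad = df.index[df["air_temp"] <= -40].tolist()
        raise ValueError(f"air temperature below physical bounds in row(s) {bad[:10]}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass
class RunConfig:
    """End-to-end run configuration; all randomness flows from ``seed``."""

    out_dir: str
    seed: int = 0
    n_demo_scenes: int = 4
    scene: Mapping = field(default_factory=dict)
    experiment: Mapping = field(default_factory=dict)
    response: str = "cwsi"
    model: str = "treatment"  # 'treatment', 'pswd', or 'both'
    scenarios: tuple = (0.0, 0.5, 1.0)
    layout_path: Optional[str] = None  # optional external region layout JSON
    log_level: str = "INFO"

    def stage_seed(self, k: int) -> int:
        return int((self.seed * 7919 + 1009 * k) % (2**31 - 1))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ValueError("config must set out_dir")
    cfg = RunConfig(**raw)
    if cfg.layout_path is not None and not Path(cfg.layout_path).exists():
        raise FileNotFoundError(f"layout file not found: {cfg.layout_path}")
    if cfg.model not in ("treatment", "pswd", "both"):
        raise ValueError("model must be 'treatment', 'pswd' or 'both'")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _fit_to_dict(fit) -> dict:
    r2m, r2c = r2_glmm(fit)
    return {
        "method": fit.method,
        "response": fit.spec.response,
        "terms": list(fit.spec.terms),
        "centering": {k: float(v) for k, v in fit.spec.centering.items()},
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "bse": {k: float(v) for k, v in fit.bse.items()},
        "sigma0_sq": fit.sigma0_sq,
        "sigma_eps_sq": fit.sigma_eps_sq,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "r2_marginal": r2m,
        "r2_conditional": r2c,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "time_scale_days": TIME_SCALE_DAYS,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest.

    A stage failure aborts the run with :class:`PipelineError` naming the
    stage; partial outputs are moved under a ``failed/`` prefix inside the
    output directory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configure"
    try:
        # ------------------------------------------------ simulate
        stage = "simulate"
        logger.info("stage simulate: experiment table + %d demo scenes", config.n_demo_scenes)
        exp_kwargs = dict(config.experiment)
        exp_kwargs.setdefault("response", config.response)
        exp_kwargs["seed"] = config.stage_seed(1)
        params = ExperimentParams(**exp_kwargs)
        model_kind = "pswd" if config.model == "pswd" else "treatment"
        obs, truth = generate_experiment(params, model=model_kind)
        obs_path = out / "observations.csv"
        write_observations(obs, obs_path)
        written.append(obs_path)
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
        written.append(truth_path)

        scene_rows = []
        scene_kwargs = dict(config.scene)
        scenes = []
        for k in range(config.n_demo_scenes):
            sp = SceneParams(**{**scene_kwargs, "seed": config.stage_seed(100 + k)})
            scene = generate_thermal_scene(sp)
            tiff = out / f"scene_{k:02d}.tif"
            scene.write(tiff, out / f"scene_{k:02d}_truth.json")
            written += [tiff, out / f"scene_{k:02d}_truth.json"]
            scenes.append((k, scene))

        # ------------------------------------------------ process images
        stage = "process-images"
        logger.info("stage process-images: segmenting %d scenes", len(scenes))
        if config.layout_path:
            layout = {k: tuple(v) for k, v in json.loads(Path(config.layout_path).read_text()).items()}
        else:
            layout = None
        seg_cfg = SegmentationConfig(emissivities={"canopy": 1.0, "wet": 1.0, "dry": 1.0})
        for k, scene in scenes:
            lay = layout or default_region_layout(scene.params)
            res = segment_scene(ThermalImage(scene.grid), seg_cfg, lay)
            logger.debug("scene %d threshold %.2f", k, res.threshold_used)
            scene_rows.append(
                {
                    "scene_id": k,
                    "t_canopy": res.median_temps["canopy"],
                    "t_wet": res.median_temps["wet"],
                    "t_dry": res.median_temps["dry"],
                    "true_canopy": scene.true_temps["canopy"],
                    "n_canopy_px": res.n_pixels["canopy"],
                    "threshold": res.threshold_used,
                }
            )
        temps = pd.DataFrame(scene_rows)
        temps_path = out / "scene_temps.csv"
        temps.to_csv(temps_path, index=False)
        written.append(temps_path)

        # ------------------------------------------------ compute indices
        stage = "compute-indices"
        if len(temps):
            temps["cwsi"] = _cwsi(temps["t_canopy"], temps["t_wet"], temps["t_dry"],
                                  warn_out_of_range=False)
            temps["ig"] = _ig(temps["t_canopy"], temps["t_wet"], temps["t_dry"],
                              warn_out_of_range=False)
            idx_path = out / "scene_indices.csv"
            temps.to_csv(idx_path, index=False)
            written.append(idx_path)

        # ------------------------------------------------ fit models
        stage = "fit-models"
        report: dict = {"seed": config.seed, "response": config.response}
        if config.model in ("treatment", "both"):
            logger.info("stage fit-models: treatment family (stress + recovery)")
            fits = {}
            for window in (STRESS_WINDOW, RECOVERY_WINDOW):
                spec = build_treatment_model(obs, window, config.response)
                spec, _ = simplify_model(spec, obs[obs["day"].isin(window.day_indices)])
                fit = fit_lmm(spec, obs[obs["day"].isin(window.day_indices)], method="REML")
                fits[window.name] = fit
            fit_path = out / "fit_treatment.json"
            fit_path.write_text(
                json.dumps({k: _fit_to_dict(v) for k, v in fits.items()}, indent=2,
                           sort_keys=True)
            )
            written.append(fit_path)
            contrasts = treatment_contrasts(fits["stress"])
            ct = pd.concat(
                [c.table.assign(family=c.family) for c in contrasts.values()],
                ignore_index=True,
            )
            ct_path = out / "contrasts_treatment.csv"
            ct.to_csv(ct_path, index=False)
            written.append(ct_path)
            if "treatment" in fits["stress"].params.index and "treatment" in fits[
                "recovery"
            ].params.index:
                report["treatment_effect_reduction"] = treatment_effect_reduction(
                    fits["stress"], fits["recovery"]
                )
            report["treatment_coef_stress"] = float(
                fits["stress"].params.get("treatment", np.nan)
            )
            deltas = response_magnitude(obs, config.response, STRESS_WINDOW)
            deltas_path = out / "response_magnitude.csv"
            deltas.to_csv(deltas_path, index=False)
            written.append(deltas_path)
        if config.model in ("pswd", "both"):
            logger.info("stage fit-models: soil-water-deficit family")
            spec = build_pswd_model(obs, config.response)
            spec, meteo_log = select_meteo_covariates(obs, spec)
            spec, _ = simplify_model(spec, obs)
            fit = fit_lmm(spec, obs, method="REML")
            fit_path = out / "fit_pswd.json"
            fit_path.write_text(
                json.dumps({"final": _fit_to_dict(fit), "meteo_selection": meteo_log},
                           indent=2, sort_keys=True)
            )
            written.append(fit_path)
            scen_tables = []
            for s in config.scenarios:
                cr = provenance_contrasts(fit, obs, at_pswd=float(s))
                scen_tables.append(cr.table.assign(family=cr.family))
            sc_path = out / "contrasts_pswd_scenarios.csv"
            pd.concat(scen_tables, ignore_index=True).to_csv(sc_path, index=False)
            written.append(sc_path)
            report["pswd_coef"] = float(fit.params.get("pswd", np.nan))

        # ------------------------------------------------ report
        stage = "report"
        index_col = config.response
        summary = (
            obs.groupby(["provenance", "treatment"], observed=True)[index_col]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        summary_path = out / "summary_by_group.csv"
        summary.to_csv(summary_path, index=False)
        written.append(summary_path)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(report_path)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "files": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete: %d artifacts in %s", len(written), out)
        return manifest
    except Exception as exc:  # pragma: no cover - exercised via tests
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                p.rename(failed / p.name)
        raise PipelineError(stage, exc) from exc
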