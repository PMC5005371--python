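"""Synthetic thermal scenes and experiment tables with known ground truth.

Two generators make every downstream stage testable without external data:

* :func:`generate_thermal_scene` renders the monitoring-platform geometry —
  heated background plates, thin needle-like canopy structures radiating
  from a stem axis, rectangular wet/dry reference targets, and a band of
  plant/background mixed pixels — and returns the ground-truth masks and
  temperatures alongside the raster.

* :func:`generate_experiment` draws a tree x measuring-day observation
  table with the random-intercept linear structure assumed by the two
  mixed-model families (soil-water-deficit response; treatment/recovery
  response), from user-named coefficients, so model fits can be judged by
  parameter recovery.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line

from . import indices as _indices
from .design import TIME_SCALE_DAYS, build_design, full_spec

__all__ = [
    "SceneParams",
    "ExperimentParams",
    "ThermalScene",
    "generate_thermal_scene",
    "generate_experiment",
    "generate_pswd_trajectories",
    "default_region_layout",
    "MEASURING_DAY_OFFSETS",
    "DEFAULT_PSWD_SCHEDULE",
    "STUDY_START",
    "TREATMENT_START",
    "TREATMENT_END",
]

# experiment calendar: 17 measuring days, roughly twice weekly, expressed as
# day offsets from the study start (pots saturated, PSWD = 0).  Measuring
# day 4 is the first day of the stress period (one week after the treatment
# started) and day 13 its last; days 14-17 form the recovery period.
STUDY_START = _dt.date(2013, 7, 5)
TREATMENT_START = _dt.date(2013, 7, 11)
TREATMENT_END = _dt.date(2013, 8, 21)
MEASURING_DAY_OFFSETS = (0, 5, 8, 12, 16, 19, 23, 26, 30, 33, 37, 43, 47, 50, 54, 57, 61)

DEFAULT_PROVENANCES = ("BG10", "D8", "ES1", "F3", "I4", "PL9")
DEFAULT_TREATMENTS = ("control", "drought")

#: deficit-positive PSWD targets per measuring day; identical across
#: treatments before the divergence day (measuring day 4), the drought group
#: then dries toward full depletion of plant-available water and both groups
#: relax after re-saturation at the start of the recovery period.
DEFAULT_PSWD_SCHEDULE: Mapping[str, Tuple[float, ...]] = {
    "control": (0.0, 0.04, 0.08, 0.12, 0.17, 0.21, 0.24, 0.27, 0.29, 0.30,
                0.31, 0.32, 0.32, 0.16, 0.12, 0.10, 0.08),
    "drought": (0.0, 0.04, 0.08, 0.30, 0.48, 0.62, 0.74, 0.83, 0.89, 0.92,
                0.94, 0.95, 0.95, 0.45, 0.38, 0.32, 0.28),
}

#: in-greenhouse envelope on measuring days (11 a.m. - 3 p.m.)
DEFAULT_METEO_RANGES: Mapping[str, Tuple[float, float]] = {
    "air_temp": (20.4, 37.1),
    "rh": (29.0, 66.0),
    "radiation": (24.0, 234.0),
}

# Default generating coefficients.  The soil-water-deficit family uses the
# headline index-vs-PSWD curvature on the deficit-positive fraction scale
# with meteorological main effects; the treatment family uses the printed
# stress-period main effects (interaction coefficients default to zero since
# the generator feeds uncentered covariates).
DEFAULT_COEFFS: Mapping[str, Mapping[str, Mapping[str, float]]] = {
    "pswd": {
        "cwsi": {"intercept": 1.00, "pswd": -2.49, "pswd2": 1.61,
                 "vpd": 0.044, "radiation": 0.00032},
        "ig": {"intercept": 0.80, "pswd": 4.39, "pswd2": -2.91,
               "vpd": -0.081, "radiation": -0.00061},
    },
    "treatment": {
        "cwsi": {"intercept": 0.45, "treatment": -0.23, "t": 0.42, "t2": -0.42,
                 "height": -0.000034, "diameter": -0.03, "air_temp": 0.0086,
                 "rh": -0.0007, "radiation": 0.00025},
        "ig": {"intercept": 0.85, "treatment": 0.43, "t": -0.54, "t2": 0.68,
               "height": 0.00014, "diameter": 0.056, "air_temp": -0.013,
               "rh": 0.0002},
    },
}


# ---------------------------------------------------------------------------
# thermal scenes


@dataclass(frozen=True)
class SceneParams:
    """Geometry and radiometry of one synthetic monitoring-platform frame."""

    image_height: int = 192
    image_width: int = 192
    canopy_temp: float = 30.0
    wet_temp: float = 22.0
    dry_temp: float = 38.0
    plate_temp: float = 40.0  # heated background plates
    noise_sd: float = 0.1
    needle_width_px: int = 4
    n_needles: int = 40
    edge_mix_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_height, self.image_width) < 32:
            raise ValueError("image dimensions must be at least 32 px")
        if self.wet_temp >= self.dry_temp:
            raise ValueError("wet reference must be cooler than dry reference")
        if self.plate_temp <= self.canopy_temp:
            raise ValueError(
                "heated plates must be strictly hotter than the canopy "
                "(contrast assumption of the segmentation)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.edge_mix_fraction <= 1):
            raise ValueError("edge_mix_fraction must lie in [0, 1]")
        if self.needle_width_px < 1:
            raise ValueError("needle width must be >= 1 px")


@dataclass
class ThermalScene:
    """Temperature raster plus ground-truth masks and region temperatures."""

    grid: np.ndarray
    masks: Dict[str, np.ndarray]
    true_temps: Dict[str, float]
    params: SceneParams

    def write(self, tiff_path, truth_path=None) -> None:
        """Write the raster as float32 TIFF with a ground-truth JSON sidecar."""
        from .imaging import write_thermal_image

        write_thermal_image(self.grid, tiff_path)
        if truth_path is not None:
            truth = {
                "true_temps": self.true_temps,
                "params": asdict(self.params),
                "mask_pixel_counts": {k: int(v.sum()) for k, v in self.masks.items()},
            }
            with open(truth_path, "w") as fh:
                json.dump(truth, fh, indent=2)


def _scene_geometry(h: int, w: int):
    """Reference rectangles and the canopy region of a frame; raises when
    the layout cannot fit."""
    ref_h = max(h // 6, 12)
    ref_w = max(w // 5, 16)
    r0 = h // 16
    wet = (r0, w // 16, r0 + ref_h, w // 16 + ref_w)
    dry = (r0, w - w // 16 - ref_w, r0 + ref_h, w - w // 16)
    canopy_top = wet[2] + 6
    if dry[1] - wet[3] < 8 or wet[1] < 0 or dry[3] > w:
        raise ValueError("degenerate geometry: reference rectangles do not fit")
    if h - canopy_top < 40:
        raise ValueError("degenerate geometry: no room for the canopy region")
    return wet, dry, canopy_top


def default_region_layout(params: SceneParams) -> Dict[str, Tuple[int, int, int, int]]:
    """Reference-rectangle layout matching :func:`generate_thermal_scene`."""
    wet, dry, _ = _scene_geometry(params.image_height, params.image_width)
    return {"wet": wet, "dry": dry}


def scene_accuracy_suite(
    n_scenes: int,
    seed: int,
    noise_range: Tuple[float, float] = (0.02, 0.15),
    edge_mix_fraction: float = 0.3,
) -> list:
    """Scene parameters for the segmentation-accuracy study.

    Per-pixel noise is drawn uniformly from ``noise_range``, bracketing the
    thermal resolution of the imaging hardware (< 0.08 K); 30% of the
    canopy-adjacent ring is mixed with the plate temperature, reproducing
    the needle-edge interference the gradient cut is meant to remove.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_scenes):
        out.append(
            SceneParams(
                noise_sd=float(rng.uniform(*noise_range)),
                edge_mix_fraction=edge_mix_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def generate_thermal_scene(params: SceneParams) -> ThermalScene:
    """Render one synthetic frame with ground truth.

    Background pixels sit at the plate temperature; the canopy is a set of
    randomly oriented 1-3 px wide needle segments radiating from a central
    stem axis (reproducing the thin-structure / mixed-pixel challenge);
    wet/dry reference rectangles are flat targets; a ring of edge pixels
    adjacent to the canopy is drawn from the mixture
    ``alpha * canopy + (1 - alpha) * plate`` with ``alpha ~ U(0.2, 0.8)``,
    each ring pixel mixed with probability ``edge_mix_fraction``.  I.i.d.
    Gaussian noise is added everywhere.  Identical parameters and seed give
    a bit-identical raster.
    """
    h, w = params.image_height, params.image_width
    wet_rect, dry_rect, canopy_top = _scene_geometry(h, w)
    rng = np.random.default_rng(params.seed)

    canopy = np.zeros((h, w), dtype=bool)
    # stem axis: 5 px wide vertical plateau so a core survives edge removal
    stem_c = w // 2
    stem_r0, stem_r1 = canopy_top + 8, h - 6
    canopy[stem_r0:stem_r1, stem_c - 2 : stem_c + 3] = True

    max_len = int(0.22 * min(h, w))
    for _ in range(params.n_needles):
        r_start = int(rng.integers(stem_r0, stem_r1))
        angle = rng.uniform(-1.4, 1.4) + (0.0 if rng.random() < 0.5 else np.pi)
        length = int(rng.integers(max(6, max_len // 2), max_len + 1))
        r_end = int(np.clip(r_start + length * np.sin(angle), canopy_top, h - 2))
        c_end = int(np.clip(stem_c + length * np.cos(angle), 1, w - 2))
        rr, cc = _draw_line(r_start, stem_c, r_end, c_end)
        seg = np.zeros((h, w), dtype=bool)
        seg[rr, cc] = True
        # needle width in px; interiors stay resolved at the rendered scale
        width = int(rng.integers(max(1, params.needle_width_px - 1),
                                 params.needle_width_px + 2))
        if width // 2 > 0:
            seg = ndimage.binary_dilation(seg, iterations=width // 2)
        canopy |= seg
    canopy[:canopy_top, :] = False

    wet = np.zeros((h, w), dtype=bool)
    wet[wet_rect[0] : wet_rect[2], wet_rect[1] : wet_rect[3]] = True
    dry = np.zeros((h, w), dtype=bool)
    dry[dry_rect[0] : dry_rect[2], dry_rect[1] : dry_rect[3]] = True
    if (canopy & (wet | dry)).any():
        raise ValueError("degenerate geometry: canopy overlaps a reference rectangle")

    ring = ndimage.binary_dilation(canopy) & ~canopy & ~wet & ~dry
    ring_idx = np.flatnonzero(ring.ravel())
    mixed_sel = rng.random(ring_idx.size) < params.edge_mix_fraction
    edge = np.zeros((h, w), dtype=bool)
    edge.ravel()[ring_idx[mixed_sel]] = True
    alphas = rng.uniform(0.2, 0.8, size=int(mixed_sel.sum()))

    grid = np.full((h, w), params.plate_temp, dtype=float)
    grid[wet] = params.wet_temp
    grid[dry] = params.dry_temp
    grid[canopy] = params.canopy_temp
    grid.ravel()[ring_idx[mixed_sel]] = (
        alphas * params.canopy_temp + (1.0 - alphas) * params.plate_temp
    )
    if params.noise_sd > 0:
        grid = grid + rng.normal(0.0, params.noise_sd, size=(h, w))

    background = ~(canopy | wet | dry | edge)
    masks = {"canopy": canopy, "wet": wet, "dry": dry, "edge": edge, "background": background}
    true_temps = {
        "canopy": params.canopy_temp,
        "wet": params.wet_temp,
        "dry": params.dry_temp,
        "plate": params.plate_temp,
    }
    return ThermalScene(grid=grid, masks=masks, true_temps=true_temps, params=params)


# ---------------------------------------------------------------------------
# experiment tables


@dataclass(frozen=True)
class ExperimentParams:
    """Design, coefficients and noise for a synthetic experiment table.

    ``n_trees`` is the count per provenance x treatment cell (the default
    balanced 4 x 6 x 2 design gives the 48 trees of the study layout).
    ``coefficients`` names the nonzero terms of the chosen model equation
    by design-column name (e.g. ``pswd``, ``pswd2``, ``provenance[ES1]``,
    ``provenance[ES1]:pswd``, ``treatment:t``); unnamed terms are zero.
    """

    n_trees: int = 4
    provenances: Tuple[str, ...] = DEFAULT_PROVENANCES
    treatments: Tuple[str, ...] = DEFAULT_TREATMENTS
    n_days: int = 17
    response: str = "cwsi"
    coefficients: Optional[Mapping[str, float]] = None
    random_intercept_sd: float = 0.05
    residual_sd: float = 0.08
    meteo_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METEO_RANGES)
    )
    pswd_schedule: Optional[Mapping[str, Sequence[float]]] = None
    pswd_jitter_sd: float = 0.04
    divergence_day: int = 4
    height_mean_mm: float = 370.0
    height_sd_mm: float = 75.0
    diameter_mean_mm: float = 8.2
    diameter_sd_mm: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0:
            raise ValueError("random intercept SD must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be > 0")
        if self.pswd_jitter_sd < 0:
            raise ValueError("PSWD jitter SD must be >= 0")
        for name, (lo, hi) in self.meteo_ranges.items():
            if hi < lo:
                raise ValueError(f"meteo range for {name} inverted")
        lo, hi = self.meteo_ranges.get("rh", (29.0, 66.0))
        if not (0 < lo <= hi <= 100):
            raise ValueError("RH range must lie in (0, 100]")
        if self.meteo_ranges.get("air_temp", (20.4, 37.1))[0] <= -40:
            raise ValueError("air temperature range below physical bounds")
        if self.response not in ("cwsi", "ig"):
            raise ValueError("response must be 'cwsi' or 'ig'")
        sched = self.pswd_schedule or DEFAULT_PSWD_SCHEDULE
        arrs = {k: np.asarray(v, dtype=float) for k, v in sched.items()}
        if len({a.shape for a in arrs.values()}) != 1:
            raise ValueError("PSWD schedule lengths differ across treatments")
        pre = slice(0, max(self.divergence_day - 1, 0))
        vals = list(arrs.values())
        for other in vals[1:]:
            if not np.allclose(vals[0][pre], other[pre]):
                raise ValueError(
                    "PSWD trajectories must be identical before the divergence day"
                )


def generate_pswd_trajectories(
    schedule: Mapping[str, Sequence[float]],
    n_trees: Mapping[str, int] | int,
    jitter_sd: float,
    seed_or_rng=0,
) -> Dict[str, np.ndarray]:
    """Per-tree PSWD series: treatment target plus a tree-level offset.

    Returns ``{treatment: array (n_trees, n_days)}``.  With zero jitter
    every tree equals its treatment target exactly.
    """
    if jitter_sd < 0:
        raise ValueError("jitter SD must be >= 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = {}
    for treatment in sorted(schedule):
        target = np.asarray(schedule[treatment], dtype=float)
        n = n_trees[treatment] if isinstance(n_trees, Mapping) else int(n_trees)
        offsets = rng.normal(0.0, jitter_sd, size=n) if jitter_sd > 0 else np.zeros(n)
        out[treatment] = target[None, :] + offsets[:, None]
    return out


def _valid_coefficient_names(kind: str, provenances: Sequence[str]) -> list:
    spec = full_spec(kind, meteo="vpd" if kind == "pswd" else "trh",
                     provenance_levels=tuple(sorted(provenances)))
    probe = pd.DataFrame(
        {
            "tree_id": ["a", "b"],
            "provenance": [sorted(provenances)[0], sorted(provenances)[-1]],
            "treatment": ["control", "drought"],
            "day_offset": [0.0, 1.0],
            "pswd": [0.0, 0.5],
            "height": [300.0, 400.0],
            "diameter": [7.0, 9.0],
            "air_temp": [25.0, 30.0],
            "rh": [40.0, 50.0],
            "vpd": [1.5, 2.5],
            "radiation": [100.0, 150.0],
        }
    )
    if kind == "pswd":
        # both meteo variants are legal coefficient targets
        _, names_vpd = build_design(spec, probe)
        spec_trh = full_spec(kind, meteo="trh", provenance_levels=tuple(sorted(provenances)))
        _, names_trh = build_design(spec_trh, probe)
        return list(dict.fromkeys(names_vpd + names_trh))
    _, names = build_design(spec, probe)
    return names


def generate_experiment(
    params: ExperimentParams, model: str = "pswd"
) -> Tuple[pd.DataFrame, Dict]:
    """Simulate a tree x measuring-day table for one model family.

    The response is ``fixed part + tree random intercept + residual`` with
    the fixed part evaluated on *uncentered* covariates (the modelling
    stage centers).  For the conductance index the linear structure lives
    on the square-root scale, so the stored ``ig`` column is the squared
    linear response.  Returns the table and a record of the true
    coefficients and variance components.
    """
    if model not in ("pswd", "treatment"):
        raise ValueError("model must be 'pswd' or 'treatment'")
    coeffs = dict(
        params.coefficients
        if params.coefficients is not None
        else DEFAULT_COEFFS[model][params.response]
    )
    valid = _valid_coefficient_names(model, params.provenances)
    unknown = sorted(set(coeffs) - set(valid))
    if unknown:
        raise ValueError(
            f"unknown coefficient name(s) {unknown}; valid names: {valid}"
        )

    rng = np.random.default_rng(params.seed)
    offsets = np.asarray(MEASURING_DAY_OFFSETS[: params.n_days], dtype=float)
    if params.n_days > len(MEASURING_DAY_OFFSETS):
        step = offsets[-1] - offsets[-2] if len(offsets) > 1 else 3.0
        extra = offsets[-1] + step * np.arange(1, params.n_days - len(offsets) + 1)
        offsets = np.concatenate([offsets, extra])
    schedule = {
        k: np.asarray(v, dtype=float)[: params.n_days]
        for k, v in (params.pswd_schedule or DEFAULT_PSWD_SCHEDULE).items()
    }

    trees = []
    for prov in params.provenances:
        for treat in params.treatments:
            for k in range(params.n_trees):
                trees.append((f"{prov}-{treat[:1]}{k + 1:02d}", prov, treat))
    n_trees = len(trees)
    heights = np.clip(
        rng.normal(params.height_mean_mm, params.height_sd_mm, n_trees), 120, None
    )
    diams = np.clip(
        rng.normal(params.diameter_mean_mm, params.diameter_sd_mm, n_trees), 3.5, None
    )
    counts = {t: sum(1 for tr in trees if tr[2] == t) for t in params.treatments}
    paths = generate_pswd_trajectories(schedule, counts, params.pswd_jitter_sd, rng)
    path_cursor = {t: 0 for t in params.treatments}
    tree_paths = []
    for _, _, treat in trees:
        tree_paths.append(paths[treat][path_cursor[treat]])
        path_cursor[treat] += 1

    rows = []
    for j in range(params.n_days):
        day_means = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in params.meteo_ranges.items()
        }
        order = rng.permutation(n_trees)
        for rank, i in enumerate(order):
            tree_id, prov, treat = trees[i]
            at = np.clip(
                day_means["air_temp"] + rng.normal(0, 0.6), *params.meteo_ranges["air_temp"]
            )
            rh = np.clip(day_means["rh"] + rng.normal(0, 1.5), *params.meteo_ranges["rh"])
            rad = np.clip(
                day_means["radiation"] + rng.normal(0, 8.0), *params.meteo_ranges["radiation"]
            )
            rows.append(
                {
                    "tree_id": tree_id,
                    "provenance": prov,
                    "treatment": treat,
                    "day": j + 1,
                    "day_offset": offsets[j],
                    "order_in_day": rank + 1,
                    "height": heights[i],
                    "diameter": diams[i],
                    "air_temp": float(at),
                    "rh": float(rh),
                    "radiation": float(rad),
                    "pswd": float(tree_paths[i][j]),
                }
            )
    df = pd.DataFrame(rows).sort_values(["tree_id", "day"], kind="stable").reset_index(drop=True)
    df["vpd"] = _indices.vpd(df["air_temp"].to_numpy(), df["rh"].to_numpy())

    # evaluate the fixed part through the same design builder the models use
    meteo = "trh" if model == "treatment" or any(
        name.startswith(("air_temp", "rh")) for name in coeffs
    ) else "vpd"
    spec = full_spec(
        model, meteo=meteo, provenance_levels=tuple(sorted(params.provenances))
    )
    X, names = build_design(spec, df)
    beta = np.array([coeffs.get(name, 0.0) for name in names])
    eta = X @ beta
    # coefficients only present in the other meteo variant
    leftover = set(coeffs) - set(names)
    if leftover:
        alt = full_spec(
            model,
            meteo="vpd" if meteo == "trh" else "trh",
            provenance_levels=tuple(sorted(params.provenances)),
        )
        Xa, na = build_design(alt, df)
        eta = eta + Xa @ np.array(
            [coeffs.get(name, 0.0) if name in leftover else 0.0 for name in na]
        )

    b_tree = rng.normal(0.0, params.random_intercept_sd, n_trees)
    tree_index = {t[0]: k for k, t in enumerate(trees)}
    b = np.array([b_tree[tree_index[t]] for t in df["tree_id"]])
    eps = rng.normal(0.0, params.residual_sd, len(df))
    linear = eta + b + eps
    if params.response == "cwsi":
        df["cwsi"] = linear
        df["ig"] = np.nan
    else:
        df["ig"] = np.clip(linear, 0.0, None) ** 2
        df["cwsi"] = np.nan

    truth = {
        "model": model,
        "response": params.response,
        "coefficients": {n: float(coeffs.get(n, 0.0)) for n in names} | {
            k: float(v) for k, v in coeffs.items() if k not in names
        },
        "random_intercept_sd": params.random_intercept_sd,
        "residual_sd": params.residual_sd,
        "seed": params.seed,
        "n_trees": n_trees,
        "n_days": params.n_days,
    }
    return df, truth
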