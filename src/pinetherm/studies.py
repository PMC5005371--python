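"""Monte-Carlo validation studies.

These routines quantify, on synthetic data with known ground truth, how
well the pipeline's stages do what they claim: segmentation accuracy of
the canopy median, confidence-interval coverage of the mixed-model
coefficients at the study's design size, type-I calibration of the
pairwise contrast procedures, and the null distribution of the
Kruskal-Wallis statistic.  The same routines back the acceptance test
suite and the reproduction script, so both always measure identical
study conditions.
"""

from __future__ import annotations

import warnings
from typing import Dict

import numpy as np
from scipy import stats

from .design import ModelSpec, default_centering
from .imaging import SegmentationConfig, ThermalImage, segment_scene
from .lmm import fit_lmm
from .stress_models import provenance_contrasts, test_interaction_curvature
from .synthetic import (
    ExperimentParams,
    default_region_layout,
    generate_experiment,
    generate_thermal_scene,
    scene_accuracy_suite,
)

__all__ = [
    "segmentation_recovery_study",
    "coverage_study",
    "contrast_calibration_study",
    "kruskal_null_study",
]

_UNIT_EPS = SegmentationConfig(emissivities={"canopy": 1.0, "wet": 1.0, "dry": 1.0})

# Table-scale generating coefficients of the deficit response used in the
# recovery studies: quadratic PSWD curvature plus meteorological effects.
_DEFICIT_COEFFS = {
    "intercept": 1.0,
    "pswd": -2.49,
    "pswd2": 1.61,
    "vpd": 0.044,
    "radiation": 0.00032,
}


def _recovery_spec(obs, terms) -> ModelSpec:
    return ModelSpec(
        response="cwsi",
        terms=terms,
        centering=default_centering(obs, terms),
        provenance_levels=tuple(sorted(obs["provenance"].unique())),
    )


def segmentation_recovery_study(
    n_scenes: int = 100, n_paired: int = 50, seed: int = 0, tol_c: float = 0.3
) -> Dict[str, float]:
    """Canopy-median recovery over the scene-accuracy suite.

    Reports the fraction of scenes whose recovered canopy median falls
    within ``tol_c`` degC of the ground truth, and the paired mean
    absolute error with and without needle-edge removal over the first
    ``n_paired`` scenes.
    """
    suite = scene_accuracy_suite(n_scenes, seed)
    errs, errs_no = [], []
    within = 0
    for k, params in enumerate(suite):
        scene = generate_thermal_scene(params)
        layout = default_region_layout(params)
        img = ThermalImage(scene.grid)
        res = segment_scene(img, _UNIT_EPS, layout)
        err = res.median_temps["canopy"] - scene.true_temps["canopy"]
        within += abs(err) <= tol_c
        if k < n_paired:
            errs.append(abs(err))
            res_no = segment_scene(img, _UNIT_EPS, layout, remove_edges=False)
            errs_no.append(abs(res_no.median_temps["canopy"] - scene.true_temps["canopy"]))
    return {
        "within_tol_rate": within / n_scenes,
        "mae_edge_removal_c": float(np.mean(errs)),
        "mae_no_removal_c": float(np.mean(errs_no)),
        "n_scenes": n_scenes,
        "n_paired": n_paired,
    }


def coverage_study(n_replicates: int = 200, seed: int = 0) -> Dict[str, float]:
    """95% CI coverage of the PSWD curvature coefficients at design scale.

    Each replicate simulates the 48-tree x 17-day deficit experiment with
    the study coefficients, refits the generating model structure by
    REML, and checks whether the Wald 95% interval covers the truth.
    """
    rng = np.random.default_rng(seed)
    terms = ("intercept", "provenance", "pswd", "pswd2", "vpd", "radiation")
    hits = {"pswd": 0, "pswd2": 0}
    for _ in range(n_replicates):
        params = ExperimentParams(
            seed=int(rng.integers(0, 2**31 - 1)), coefficients=_DEFICIT_COEFFS
        )
        obs, truth = generate_experiment(params, model="pswd")
        fit = fit_lmm(_recovery_spec(obs, terms), obs, method="REML")
        for name in hits:
            lo = fit.params[name] - 1.96 * fit.bse[name]
            hi = fit.params[name] + 1.96 * fit.bse[name]
            hits[name] += lo <= truth["coefficients"][name] <= hi
    return {
        "coverage_pswd": hits["pswd"] / n_replicates,
        "coverage_pswd2": hits["pswd2"] / n_replicates,
        "n_replicates": n_replicates,
    }


def contrast_calibration_study(
    n_sims: int = 500, seed: int = 0, alpha: float = 0.05
) -> Dict[str, float]:
    """Type-I error of the scenario and curvature contrast procedures.

    Simulates complete-null experiments (no provenance differences, no
    PSWD-provenance interaction) at a 24-tree x 8-day design, runs the
    FDR-adjusted provenance contrasts at the 50% deficit scenario and the
    joint curvature tests, and reports per-contrast rejection rates on
    both adjusted and raw p-values.
    """
    rng = np.random.default_rng(seed)
    terms = (
        "intercept", "provenance", "pswd", "pswd2",
        "provenance:pswd", "provenance:pswd2",
    )
    rej_adj = rej_raw = n_contrasts = 0
    rej_curv_adj = n_curv = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            params = ExperimentParams(
                n_trees=2,
                n_days=8,
                seed=int(rng.integers(0, 2**31 - 1)),
                coefficients={"intercept": 0.5, "pswd": -2.49, "pswd2": 1.61},
            )
            obs, _ = generate_experiment(params, model="pswd")
            fit = fit_lmm(_recovery_spec(obs, terms), obs, method="REML")
            scen = provenance_contrasts(fit, obs, at_pswd=0.5).table
            rej_adj += int((scen["p_adj"] < alpha).sum())
            rej_raw += int((scen["p_raw"] < alpha).sum())
            n_contrasts += len(scen)
            curv = test_interaction_curvature(fit).table
            rej_curv_adj += int((curv["p_adj"] < alpha).sum())
            n_curv += len(curv)
    return {
        "scenario_type1_adjusted": rej_adj / n_contrasts,
        "scenario_type1_raw": rej_raw / n_contrasts,
        "curvature_type1_adjusted": rej_curv_adj / n_curv,
        "n_sims": n_sims,
    }


def kruskal_null_study(
    n_sims: int = 2000, seed: int = 0, k_groups: int = 4, group_size: int = 10
) -> Dict[str, float]:
    """Null distribution of the Kruskal-Wallis H against chi-square.

    All groups are drawn from one distribution; the Kolmogorov distance
    between the simulated H values and the chi-square reference with
    ``k_groups - 1`` degrees of freedom measures the calibration of the
    test at the study's group sizes.
    """
    rng = np.random.default_rng(seed)
    hs = np.empty(n_sims)
    for i in range(n_sims):
        samples = [rng.normal(0, 1, group_size) for _ in range(k_groups)]
        hs[i] = stats.kruskal(*samples).statistic
    ks = stats.kstest(hs, stats.chi2(k_groups - 1).cdf).statistic
    return {"ks_distance": float(ks), "n_sims": n_sims, "df": k_groups - 1}
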