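"""Soil-water-deficit mixed-model analysis.

Workflow: build the full index-vs-PSWD model (random intercept per tree,
PSWD linear + quadratic uncentered, every other covariate mean-centered),
choose between the {air temperature + relative humidity} and {VPD} meteo
covariate sets by ML-AIC, simplify by backward single-term deletion
(drop1 under ML-AIC, respecting marginality), then report the REML fit,
Nakagawa-Schielzeth R^2, pairwise provenance contrasts under re-centered
PSWD scenarios, and joint tests on the linear + quadratic PSWD-provenance
interaction coefficients.  All multiple comparisons are BH-FDR adjusted.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, default_centering, full_spec
from .lmm import (
    ContrastResult,
    ModelFit,
    bh_adjust,
    fit_lmm,
    pairwise_z_contrasts,
    r2_glmm,
)

__all__ = [
    "build_pswd_model",
    "fit_lmm",
    "r2_glmm",
    "select_meteo_covariates",
    "select_variance_structure",
    "simplify_model",
    "provenance_contrasts",
    "test_interaction_curvature",
]

_REQUIRED_COLUMNS = (
    "tree_id", "provenance", "treatment", "day", "pswd",
    "height", "diameter", "air_temp", "rh", "vpd", "radiation",
)


def _check_columns(obs: pd.DataFrame, needed) -> None:
    for col in needed:
        if col not in obs.columns:
            raise KeyError(f"observation table is missing required column {col!r}")


def build_pswd_model(
    obs: pd.DataFrame, response: str = "cwsi", *, meteo: str = "vpd"
) -> ModelSpec:
    """Full soil-water-deficit model specification for an observation table.

    PSWD stays uncentered (its scenario contrasts re-center explicitly);
    all other covariates are centered on the means of ``obs``, and the
    means actually used are stored on the spec so any fit can be
    reproduced exactly.
    """
    _check_columns(obs, _REQUIRED_COLUMNS)
    if obs["tree_id"].nunique() < 2:
        raise ValueError("random intercept unidentifiable: need at least 2 trees")
    levels = tuple(sorted(obs["provenance"].unique()))
    if len(levels) < 2:
        raise ValueError("need at least 2 provenances to model provenance effects")
    resp = "sqrt_ig" if response in ("ig", "sqrt_ig") else "cwsi"
    spec = full_spec("pswd", resp, meteo=meteo, provenance_levels=levels)
    centering = default_centering(obs, spec.terms)
    return spec.with_centering(**centering)


def select_meteo_covariates(
    obs: pd.DataFrame, base_spec: ModelSpec
) -> Tuple[ModelSpec, dict]:
    """Choose {air temperature + RH} vs {VPD} by ML-AIC; ties go to VPD.

    The two candidate variables sets are strongly correlated, so only one
    enters the model.  Returns the winning spec and the AIC bookkeeping.
    """
    spec_vpd = build_pswd_model(obs, base_spec.response, meteo="vpd")
    spec_trh = build_pswd_model(obs, base_spec.response, meteo="trh")
    fit_vpd = fit_lmm(spec_vpd, obs, method="ML")
    fit_trh = fit_lmm(spec_trh, obs, method="ML")
    choice = "vpd" if fit_vpd.aic <= fit_trh.aic else "trh"
    winner = spec_vpd if choice == "vpd" else spec_trh
    return winner, {"aic_vpd": fit_vpd.aic, "aic_trh": fit_trh.aic, "choice": choice}


def select_variance_structure(
    spec: ModelSpec, obs: pd.DataFrame, structures=("homoscedastic", "per_treatment", "power")
) -> Tuple[ModelSpec, dict]:
    """Pick the residual variance-function class by ML-AIC."""
    from dataclasses import replace

    aics = {}
    best = None
    for s in structures:
        candidate = replace(spec, variance_structure=s)
        aics[s] = fit_lmm(candidate, obs, method="ML").aic
        if best is None or aics[s] < aics[best]:
            best = s
    return replace(spec, variance_structure=best), aics


def simplify_model(
    spec: ModelSpec, obs: pd.DataFrame
) -> Tuple[ModelSpec, pd.DataFrame]:
    """Backward single-term deletion under ML-AIC (drop1), with log.

    At each step every term whose removal respects marginality is refit
    without; the deletion lowering AIC the most is applied; iteration
    stops when no single deletion lowers the AIC.
    """
    current = spec
    current_aic = fit_lmm(current, obs, method="ML").aic
    log_rows = []
    improved = True
    while improved:
        improved = False
        candidates = []
        for term in current.droppable_terms():
            reduced = current.drop(term)
            try:
                aic = fit_lmm(reduced, obs, method="ML").aic
            except (ValueError, np.linalg.LinAlgError):
                continue
            candidates.append((term, aic))
            log_rows.append({"step": len(log_rows), "term": term, "aic_without": aic,
                             "aic_with": current_aic, "dropped": False})
        if candidates:
            term, aic = min(candidates, key=lambda t: t[1])
            if aic < current_aic:
                current = current.drop(term)
                current_aic = aic
                log_rows[-len(candidates) + [c[0] for c in candidates].index(term)][
                    "dropped"
                ] = True
                improved = True
    return current, pd.DataFrame(log_rows)


def _provenance_effect_vectors(fit: ModelFit, suffix: str = "") -> dict:
    """Contrast vectors of provenance effects (reference level = zeros)."""
    names = list(fit.params.index)
    levels = fit.spec.provenance_levels or ()
    out = {}
    for lvl in levels:
        vec = np.zeros(len(names))
        key = f"provenance[{lvl}]{suffix}"
        if key in names:
            vec[names.index(key)] = 1.0
        out[lvl] = vec
    return out


def provenance_contrasts(
    fit: ModelFit, obs: pd.DataFrame, at_pswd: float = 0.0
) -> ContrastResult:
    """Pairwise provenance contrasts under a PSWD scenario.

    Re-centers PSWD at ``at_pswd`` (a deficit fraction: 0, 0.5, 1.0 are the
    standard scenarios), refits with the same method, then z-tests all
    provenance pairs on the provenance main effects with BH-FDR adjustment.
    At the re-centered origin the provenance dummies measure provenance
    differences *at that soil-water deficit*.
    """
    if "provenance" not in fit.spec.terms:
        raise ValueError("no provenance term in the fitted model to contrast")
    spec = fit.spec.with_centering(pswd=float(at_pswd))
    refit = fit_lmm(spec, obs, method=fit.method)
    effects = _provenance_effect_vectors(refit)
    result = pairwise_z_contrasts(refit, effects, family=f"provenance@pswd={at_pswd:g}")
    return result


def test_interaction_curvature(fit: ModelFit) -> ContrastResult:
    """Joint 2-df Wald tests on provenance-pair differences of the linear and
    quadratic PSWD-interaction coefficients, BH-FDR adjusted.

    Raises when the fitted model carries no PSWD-provenance interaction.
    """
    if "provenance:pswd" not in fit.spec.terms and "provenance:pswd2" not in fit.spec.terms:
        raise ValueError("no interaction to test: model lacks provenance x PSWD terms")
    names = list(fit.params.index)
    levels = fit.spec.provenance_levels
    rows = []
    for a, b in itertools.combinations(levels, 2):
        C = []
        for suffix in (":pswd", ":pswd2"):
            vec = np.zeros(len(names))
            ka, kb = f"provenance[{a}]{suffix}", f"provenance[{b}]{suffix}"
            if ka in names:
                vec[names.index(ka)] = 1.0
            if kb in names:
                vec[names.index(kb)] = -1.0
            if np.any(vec):
                C.append(vec)
        if not C:
            continue
        stat, df, p = fit.wald(np.array(C))
        rows.append({"a": a, "b": b, "estimate": np.nan, "se": np.nan,
                     "stat": stat, "df": df, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return ContrastResult(family="pswd-provenance curvature", table=table)
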