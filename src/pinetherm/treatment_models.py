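"""Treatment / recovery mixed-model analysis and the response-magnitude
procedure.

The drought experiment is analyzed in two disjoint windows: the stress
period (measuring days 4-13, once the two irrigation regimes had clearly
separated the soil-water deficits) and the recovery period (days 14-17,
after re-saturation).  Within each window a random-intercept model relates
the thermal index to a treatment dummy (drought = 0, control = 1), linear
and quadratic time, seedling dimensions, meteorology, and the
treatment-interaction set; pairwise post-hoc contrasts and the
non-parametric response-magnitude analysis (Kruskal-Wallis + Dunn) follow,
all BH-FDR adjusted per family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, default_centering, full_spec
from .lmm import ContrastResult, ModelFit, bh_adjust, fit_lmm, pairwise_z_contrasts

__all__ = [
    "PeriodWindow",
    "STRESS_WINDOW",
    "RECOVERY_WINDOW",
    "build_treatment_model",
    "treatment_contrasts",
    "treatment_effect_reduction",
    "response_magnitude",
    "kruskal_dunn",
]


@dataclass(frozen=True)
class PeriodWindow:
    """A named, disjoint block of measuring days (1-17)."""

    name: str
    day_indices: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.day_indices:
            raise ValueError("empty period window")
        if any(d < 1 or d > 17 for d in self.day_indices):
            raise ValueError("measuring-day indices must lie in 1..17")


STRESS_WINDOW = PeriodWindow("stress", tuple(range(4, 14)))
RECOVERY_WINDOW = PeriodWindow("recovery", (14, 15, 16, 17))


def subset_window(obs: pd.DataFrame, window: PeriodWindow) -> pd.DataFrame:
    sub = obs[obs["day"].isin(window.day_indices)]
    if sub.empty:
        raise ValueError(f"no observations fall in the {window.name} window")
    return sub


def build_treatment_model(
    obs: pd.DataFrame, window: PeriodWindow, response: str = "cwsi"
) -> ModelSpec:
    """Full treatment-period model spec, centered within the window.

    The treatment dummy codes drought = 0 and control = 1; time enters as
    days since the study start scaled by the 42-day treatment-window
    length, linear plus quadratic; covariates (including time) are
    centered on their window means.
    """
    sub = subset_window(obs, window)
    if sub["treatment"].nunique() < 2:
        raise ValueError(f"{window.name} window contains a single treatment only")
    levels = tuple(sorted(sub["provenance"].unique()))
    resp = "sqrt_ig" if response in ("ig", "sqrt_ig") else "cwsi"
    spec = full_spec("treatment", resp, provenance_levels=levels)
    if len(levels) < 2:
        # single provenance: no provenance terms are estimable
        spec = spec.drop("provenance:treatment").drop("provenance")
    centering = default_centering(sub, spec.terms)
    return spec.with_centering(**centering)


def treatment_contrasts(fit: ModelFit) -> Dict[str, ContrastResult]:
    """Post-hoc contrast families for a fitted treatment-period model.

    * ``treatment_within_provenance`` — control minus drought per
      provenance (treatment main effect plus that provenance's
      interaction, when present);
    * ``provenance_within_drought`` / ``provenance_within_control`` — all
      provenance pairs within each treatment group.

    BH-FDR adjustment is applied within each family separately.
    """
    names = list(fit.params.index)
    levels = fit.spec.provenance_levels or ()
    p = len(names)

    def unit(name: str) -> np.ndarray:
        vec = np.zeros(p)
        if name in names:
            vec[names.index(name)] = 1.0
        return vec

    out: Dict[str, ContrastResult] = {}

    rows = []
    prov_iter = levels if len(levels) >= 1 else ("all",)
    for lvl in prov_iter:
        c = unit("treatment") + unit(f"provenance[{lvl}]:treatment")
        est, se, z, pr = fit.contrast(c)
        rows.append({"a": f"{lvl}:control", "b": f"{lvl}:drought", "estimate": est,
                     "se": se, "stat": z, "df": 1, "p_raw": pr})
    tab = pd.DataFrame(rows)
    tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
    out["treatment_within_provenance"] = ContrastResult("treatment_within_provenance", tab)

    if len(levels) >= 2:
        drought_eff = {lvl: unit(f"provenance[{lvl}]") for lvl in levels}
        out["provenance_within_drought"] = pairwise_z_contrasts(
            fit, drought_eff, "provenance_within_drought"
        )
        control_eff = {
            lvl: unit(f"provenance[{lvl}]") + unit(f"provenance[{lvl}]:treatment")
            for lvl in levels
        }
        out["provenance_within_control"] = pairwise_z_contrasts(
            fit, control_eff, "provenance_within_control"
        )
    return out


def treatment_effect_reduction(
    stress: Union[ModelFit, float], recovery: Union[ModelFit, float]
) -> Dict[str, float]:
    """How much the treatment gap shrinks from stress to recovery.

    ``100 * (1 - |beta_recovery| / |beta_stress|)`` as a percentage, plus
    the value rounded to the nearest ten percent.  Accepts fitted models
    (their ``treatment`` coefficients are extracted) or raw coefficients.
    """

    def coef(x) -> float:
        if isinstance(x, ModelFit):
            if "treatment" not in x.params.index:
                raise ValueError("fit contains no treatment coefficient")
            return float(x.params["treatment"])
        return float(x)

    b_s, b_r = coef(stress), coef(recovery)
    if b_s == 0:
        raise ValueError("stress-period treatment coefficient is zero")
    pct = 100.0 * (1.0 - abs(b_r) / abs(b_s))
    return {"percent": pct, "rounded_to_ten": 10.0 * round(pct / 10.0)}


def response_magnitude(
    obs: pd.DataFrame,
    index: str = "cwsi",
    window: PeriodWindow = STRESS_WINDOW,
    min_days: int = 3,
) -> pd.DataFrame:
    """Pairwise drought-minus-control index differences within provenance.

    Individual trees are first averaged over the window; every drought
    tree is then paired with every control tree of the same provenance.
    Provenances lacking either treatment group are excluded with a
    warning; trees with fewer than ``min_days`` usable measuring days are
    dropped.
    """
    sub = subset_window(obs, window)
    if index not in sub.columns:
        raise KeyError(f"observation table is missing index column {index!r}")
    per_tree = (
        sub.dropna(subset=[index])
        .groupby(["provenance", "treatment", "tree_id"], observed=True)[index]
        .agg(["mean", "count"])
        .reset_index()
    )
    few = per_tree["count"] < min_days
    if few.any():
        warnings.warn(
            f"dropping {int(few.sum())} tree(s) with < {min_days} measuring days",
            stacklevel=2,
        )
        per_tree = per_tree[~few]
    rows = []
    for prov, block in per_tree.groupby("provenance", observed=True):
        drought = block[block["treatment"] == "drought"]
        control = block[block["treatment"] == "control"]
        if drought.empty or control.empty:
            warnings.warn(
                f"provenance {prov}: missing a treatment group; excluded", stacklevel=2
            )
            continue
        for _, d in drought.iterrows():
            for _, c in control.iterrows():
                rows.append(
                    {
                        "provenance": prov,
                        "drought_tree_id": d["tree_id"],
                        "control_tree_id": c["tree_id"],
                        "delta_index": d["mean"] - c["mean"],
                    }
                )
    return pd.DataFrame(rows)


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise z-tests.

    Dunn's statistics use the pooled-rank means with the standard
    tie-corrected variance; pairwise p-values are BH-FDR adjusted.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for k, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    H, p_kw = stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for k, s in zip(labels, samples):
        mean_ranks[k] = float(ranks[start : start + len(s)].mean())
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    rows = []
    sizes = {k: len(s) for k, s in zip(labels, samples)}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"a": a, "b": b, "estimate": mean_ranks[a] - mean_ranks[b],
                     "se": se, "stat": z, "df": 1, "p_raw": 2 * stats.norm.sf(abs(z))})
    dunn = pd.DataFrame(rows)
    dunn["p_adj"] = bh_adjust(dunn["p_raw"].to_numpy())
    return {"H": float(H), "p_kruskal": float(p_kw), "mean_ranks": mean_ranks, "dunn": dunn}
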