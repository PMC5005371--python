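"""Model specifications and design-matrix construction for the two
mixed-model families.

Two model kinds are supported:

``pswd``
    index ~ provenance + PSWD + PSWD^2 + height + diameter +
    {VPD | airT + RH} + radiation + provenance:PSWD(^2) + meteo:PSWD,
    with a random intercept per tree.  PSWD enters uncentered (linear and
    quadratic); every other covariate is mean-centered.

``treatment``
    index ~ provenance + treatment + t + t^2 + height + diameter + airT +
    RH + radiation + provenance:treatment + treatment:{t, t^2, height,
    diameter, airT, RH}.  The treatment dummy codes drought = 0,
    control = 1; ``t`` is days since the study start scaled by 1/42 (the
    treatment-window length), then centered.

Provenance dummies use the alphabetically first level as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

#: days between consecutive calendar days, used to scale the time covariate
TIME_SCALE_DAYS = 42.0

#: continuous covariates that the modelling stage centers on their means
CENTERED_COVARIATES = ("height", "diameter", "air_temp", "rh", "vpd", "radiation", "t")

#: interaction / polynomial marginality: term -> parent terms
MARGINALITY = {
    "pswd2": ("pswd",),
    "t2": ("t",),
    "provenance:pswd": ("provenance", "pswd"),
    "provenance:pswd2": ("provenance", "pswd2"),
    "vpd:pswd": ("vpd", "pswd"),
    "air_temp:pswd": ("air_temp", "pswd"),
    "rh:pswd": ("rh", "pswd"),
    "provenance:treatment": ("provenance", "treatment"),
    "treatment:t": ("treatment", "t"),
    "treatment:t2": ("treatment", "t2"),
    "treatment:height": ("treatment", "height"),
    "treatment:diameter": ("treatment", "diameter"),
    "treatment:air_temp": ("treatment", "air_temp"),
    "treatment:rh": ("treatment", "rh"),
}

PSWD_TERMS = (
    "intercept",
    "provenance",
    "pswd",
    "pswd2",
    "height",
    "diameter",
    "vpd",
    "radiation",
    "provenance:pswd",
    "provenance:pswd2",
    "vpd:pswd",
)

PSWD_TERMS_TRH = (
    "intercept",
    "provenance",
    "pswd",
    "pswd2",
    "height",
    "diameter",
    "air_temp",
    "rh",
    "radiation",
    "provenance:pswd",
    "provenance:pswd2",
    "air_temp:pswd",
    "rh:pswd",
)

TREATMENT_TERMS = (
    "intercept",
    "provenance",
    "treatment",
    "t",
    "t2",
    "height",
    "diameter",
    "air_temp",
    "rh",
    "radiation",
    "provenance:treatment",
    "treatment:t",
    "treatment:t2",
    "treatment:height",
    "treatment:diameter",
    "treatment:air_temp",
    "treatment:rh",
)

VARIANCE_STRUCTURES = ("homoscedastic", "per_treatment", "power")


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects term set plus centering and variance-structure choices.

    ``centering`` maps covariate name -> center value actually subtracted;
    storing the means used makes a fit exactly reproducible and allows the
    PSWD-scenario contrasts to re-center and refit.
    """

    response: str  # 'cwsi' or 'sqrt_ig'
    terms: Tuple[str, ...]
    centering: Mapping[str, float] = field(default_factory=dict)
    variance_structure: str = "homoscedastic"
    provenance_levels: Tuple[str, ...] = ()
    kind: str = "pswd"

    def __post_init__(self) -> None:
        if self.response not in ("cwsi", "sqrt_ig"):
            raise ValueError("response must be 'cwsi' or 'sqrt_ig'")
        if self.variance_structure not in VARIANCE_STRUCTURES:
            raise ValueError(f"unknown variance structure {self.variance_structure!r}")
        for t in self.terms:
            for parent in MARGINALITY.get(t, ()):
                if parent not in self.terms:
                    raise ValueError(f"term {t!r} requires its parent {parent!r}")
        has_vpd = "vpd" in self.terms
        has_trh = "air_temp" in self.terms or "rh" in self.terms
        if has_vpd and has_trh:
            raise ValueError("use either VPD or air temperature + RH, not both")

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def with_centering(self, **updates: float) -> "ModelSpec":
        c = dict(self.centering)
        c.update(updates)
        return replace(self, centering=c)

    def droppable_terms(self) -> Tuple[str, ...]:
        """Terms removable in a single backward-deletion step (marginality)."""
        out = []
        for t in self.terms:
            if t == "intercept":
                continue
            if any(t in MARGINALITY.get(other, ()) for other in self.terms if other != t):
                continue
            out.append(t)
        return tuple(out)


def full_spec(
    kind: str,
    response: str = "cwsi",
    *,
    meteo: str = "vpd",
    provenance_levels: Sequence[str] = (),
    centering: Mapping[str, float] | None = None,
    variance_structure: str = "homoscedastic",
) -> ModelSpec:
    if kind == "pswd":
        terms = PSWD_TERMS if meteo == "vpd" else PSWD_TERMS_TRH
    elif kind == "treatment":
        terms = TREATMENT_TERMS
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return ModelSpec(
        response=response,
        terms=terms,
        centering=dict(centering or {}),
        variance_structure=variance_structure,
        provenance_levels=tuple(provenance_levels),
        kind=kind,
    )


def _covariate(df: pd.DataFrame, name: str, centering: Mapping[str, float]) -> np.ndarray:
    if name == "t":
        base = df["day_offset"].to_numpy(dtype=float) / TIME_SCALE_DAYS
    else:
        if name not in df.columns:
            raise KeyError(f"observation table is missing required column {name!r}")
        base = df[name].to_numpy(dtype=float)
    return base - float(centering.get(name, 0.0))


def _treatment_dummy(df: pd.DataFrame) -> np.ndarray:
    # drought = 0, control = 1
    return (df["treatment"].to_numpy() == "control").astype(float)


def build_design(spec: ModelSpec, df: pd.DataFrame) -> Tuple[np.ndarray, list]:
    """Build the fixed-effects design matrix and column names for ``spec``."""
    n = len(df)
    levels = spec.provenance_levels or tuple(sorted(df["provenance"].unique()))
    cols: list[np.ndarray] = []
    names: list[str] = []

    def prov_dummies() -> list:
        out = []
        prov = df["provenance"].to_numpy()
        for lvl in levels[1:]:
            out.append((lvl, (prov == lvl).astype(float)))
        return out

    for term in spec.terms:
        if term == "intercept":
            cols.append(np.ones(n))
            names.append("intercept")
        elif term == "provenance":
            for lvl, d in prov_dummies():
                cols.append(d)
                names.append(f"provenance[{lvl}]")
        elif term == "treatment":
            cols.append(_treatment_dummy(df))
            names.append("treatment")
        elif term in ("pswd", "height", "diameter", "air_temp", "rh", "vpd", "radiation", "t"):
            cols.append(_covariate(df, term, spec.centering))
            names.append(term)
        elif term == "pswd2":
            cols.append(_covariate(df, "pswd", spec.centering) ** 2)
            names.append("pswd2")
        elif term == "t2":
            cols.append(_covariate(df, "t", spec.centering) ** 2)
            names.append("t2")
        elif term in ("provenance:pswd", "provenance:pswd2"):
            power = 2 if term.endswith("2") else 1
            p = _covariate(df, "pswd", spec.centering) ** power
            for lvl, d in prov_dummies():
                cols.append(d * p)
                names.append(f"provenance[{lvl}]:{'pswd2' if power == 2 else 'pswd'}")
        elif term == "provenance:treatment":
            tr = _treatment_dummy(df)
            for lvl, d in prov_dummies():
                cols.append(d * tr)
                names.append(f"provenance[{lvl}]:treatment")
        elif term in ("vpd:pswd", "air_temp:pswd", "rh:pswd"):
            cov = term.split(":")[0]
            cols.append(
                _covariate(df, cov, spec.centering) * _covariate(df, "pswd", spec.centering)
            )
            names.append(term)
        elif term.startswith("treatment:"):
            cov = term.split(":")[1]
            tr = _treatment_dummy(df)
            if cov == "t2":
                x = _covariate(df, "t", spec.centering) ** 2
            else:
                x = _covariate(df, cov, spec.centering)
            cols.append(tr * x)
            names.append(term)
        else:
            raise ValueError(f"unknown model term {term!r}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def build_response(spec: ModelSpec, df: pd.DataFrame) -> np.ndarray:
    """Response vector; the conductance index is square-root transformed."""
    if spec.response == "cwsi":
        if "cwsi" not in df.columns:
            raise KeyError("observation table is missing required column 'cwsi'")
        return df["cwsi"].to_numpy(dtype=float)
    igv = df["ig"].to_numpy(dtype=float)
    neg = np.flatnonzero(igv < 0)
    if neg.size:
        raise ValueError(f"Ig negative in rows {neg.tolist()[:10]}; sqrt transform undefined")
    return np.sqrt(igv)


def default_centering(df: pd.DataFrame, terms: Sequence[str]) -> dict:
    """Mean-centering map for every centered covariate appearing in ``terms``.

    PSWD is deliberately left uncentered (scenario contrasts re-center it
    explicitly); the time covariate is centered on its scaled mean.
    """
    needed = set()
    for t in terms:
        for part in t.split(":"):
            if part in CENTERED_COVARIATES:
                needed.add(part)
            if part == "t2":
                needed.add("t")
    out = {}
    for cov in sorted(needed):
        if cov == "t":
            out["t"] = float(df["day_offset"].mean() / TIME_SCALE_DAYS)
        else:
            if cov not in df.columns:
                raise KeyError(f"observation table is missing required column {cov!r}")
            out[cov] = float(df[cov].mean())
    return out
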