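"""Thermal stress indices and environmental covariates.

The two indices normalize canopy surface temperature against artificial
reference surfaces imaged in the same frame: a wet reference emulating a
maximally transpiring leaf and a dry reference emulating a non-transpiring
one.  ``CWSI`` runs from 0 (fully transpiring, canopy at the wet reference)
to 1 (non-transpiring, canopy at the dry reference); ``Ig`` is linearly
related to stomatal conductance and decreases with stress.

Also provided: FAO-56 vapor pressure deficit, percent soil water deficit
from pot weighings, and irrigation-schedule bookkeeping.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "cwsi",
    "ig",
    "vpd",
    "pswd",
    "PotWeightRecord",
    "irrigation_summary",
    "window_length_days",
]


def _asarray(x):
    return np.asarray(x, dtype=float)


def cwsi(t_canopy, t_wet, t_dry, *, warn_out_of_range: bool = True):
    """Crop water stress index ``(T_canopy - T_wet) / (T_dry - T_wet)``.

    Parameters are temperatures in degC (scalar or array, broadcastable).
    Values outside [0, 1] are physically possible (the canopy may run
    cooler than the wet or hotter than the dry reference) and are retained
    with a warning rather than clipped: clipping would bias downstream
    regression models.

    Raises
    ------
    ValueError
        If ``t_dry <= t_wet`` anywhere ("reference inversion").
    """
    tc, tw, td = _asarray(t_canopy), _asarray(t_wet), _asarray(t_dry)
    if not (np.isfinite(tc).all() and np.isfinite(tw).all() and np.isfinite(td).all()):
        raise ValueError("non-finite temperature input")
    if np.any(td <= tw):
        raise ValueError("reference inversion: t_dry must be strictly above t_wet")
    out = (tc - tw) / (td - tw)
    if warn_out_of_range and np.any((out < 0) | (out > 1)):
        warnings.warn("CWSI outside [0, 1]; values retained unclipped", stacklevel=2)
    return out if out.ndim else float(out)


def ig(t_canopy, t_wet, t_dry, *, warn_out_of_range: bool = True):
    """Stomatal conductance index ``(T_dry - T_canopy) / (T_canopy - T_wet)``.

    Satisfies ``ig = (1 - cwsi) / cwsi`` wherever both are defined.

    Raises
    ------
    ValueError
        If ``t_canopy <= t_wet`` anywhere (denominator nonpositive).
    """
    tc, tw, td = _asarray(t_canopy), _asarray(t_wet), _asarray(t_dry)
    if not (np.isfinite(tc).all() and np.isfinite(tw).all() and np.isfinite(td).all()):
        raise ValueError("non-finite temperature input")
    if np.any(tc <= tw):
        raise ValueError("denominator nonpositive: t_canopy must exceed t_wet")
    out = (td - tc) / (tc - tw)
    if warn_out_of_range and np.any(out < 0):
        warnings.warn("Ig below 0 (canopy above dry reference); retained", stacklevel=2)
    return out if out.ndim else float(out)


def vpd(air_temp, rh):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%).

    FAO-56 form: ``e_s = 0.6108 * exp(17.27 T / (T + 237.3))`` and
    ``e_a = (RH/100) * e_s``; VPD is ``e_s - e_a``.  Strictly increasing in
    temperature for fixed RH < 100, and exactly zero at saturation.
    """
    t, h = _asarray(air_temp), _asarray(rh)
    if np.any((h <= 0) | (h > 100)):
        raise ValueError("relative humidity must lie in (0, 100]")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = es * (1.0 - h / 100.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PotWeightRecord:
    """One pot weighing: actual weight vs. the field-capacity baseline (g).

    ``water_content_fc`` is the absolute plant-available water content at
    field capacity (derived from the water retention curve; 40% of
    substrate at 10 kPa matrix potential for the peat used here).
    """

    tree_id: str
    day: int
    weight_actual: float
    weight_field_capacity: float
    water_content_fc: float

    def __post_init__(self) -> None:
        if self.weight_actual <= 0 or self.weight_field_capacity <= 0:
            raise ValueError("pot weights must be positive")
        if self.water_content_fc > self.weight_field_capacity:
            raise ValueError("water content at field capacity cannot exceed pot weight")


def pswd(rec_or_weight_fc, weight_actual=None, water_content_fc=None):
    """Percent soil water deficit as a deficit-positive fraction.

    ``(weight_at_field_capacity - weight_actual) / water_content_at_fc``:
    0 at field capacity, 1 when the whole plant-available water has been
    depleted, negative when over-saturated.  Accepts a
    :class:`PotWeightRecord` or the three weights directly.
    """
    if isinstance(rec_or_weight_fc, PotWeightRecord):
        rec = rec_or_weight_fc
        wfc, wa, cfc = rec.weight_field_capacity, rec.weight_actual, rec.water_content_fc
    else:
        wfc, wa, cfc = rec_or_weight_fc, weight_actual, water_content_fc
    wfc, wa, cfc = _asarray(wfc), _asarray(wa), _asarray(cfc)
    if np.any(cfc <= 0):
        raise ValueError("water content at field capacity must be positive")
    out = (wfc - wa) / cfc
    return out if out.ndim else float(out)


def irrigation_summary(control_ml: float, drought_ml: float) -> dict:
    """Cumulative irrigation totals and the drought/control percentage.

    Returns the two totals plus ``drought_pct_of_control`` rounded to the
    nearest integer percent.
    """
    if control_ml < 0 or drought_ml < 0:
        raise ValueError("irrigation volumes must be nonnegative")
    if control_ml == 0:
        raise ValueError("control irrigation total is zero")
    pct = int(round(100.0 * drought_ml / control_ml))
    return {
        "control_total_ml": float(control_ml),
        "drought_total_ml": float(drought_ml),
        "drought_pct_of_control": pct,
    }


def window_length_days(start: _dt.date, end: _dt.date) -> int:
    """Length of a treatment window in days, both endpoints inclusive."""
    if end < start:
        raise ValueError("window end precedes start")
    return (end - start).days + 1
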