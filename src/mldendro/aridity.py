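"""Annual aridity indices from Walter-Lieth climate diagrams.

A Walter-Lieth diagram overlays monthly cumulative precipitation P (mm)
with an evaporation proxy E = 2*T built from monthly mean temperature
(1 degC of monthly temperature amounts to 2 mm/month of evaporation).
Periods with E > P are dry, periods with P > E are wet, and the annual
aridity index is the ratio of the dry to the wet area between the two
curves over one (seasonal) year.  A square-root transformation of the
index is approximately stationary and is the default downstream.

Both curves are piecewise linear through the twelve month midpoints
(equal-width month intervals, December/January wrapped), and the dry
and wet areas are integrated segment by segment in closed form, which
is the exact limit of trapezoid integration on an ever finer grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .hierdata import HierSeries

__all__ = ["wlai", "wl_curves", "aridity_table"]

#: Ratio between evaporation (mm/month) and monthly mean temperature (degC).
EVAPORATION_PER_DEGC = 2.0


def _breakpoints(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear curve through month midpoints on [0, 12].

    Month i (seasonal order) occupies [i, i+1] with its value at the
    midpoint i + 0.5; the year edges take the December/January wrap
    value (the linear continuation between the last and first months).
    """
    v = np.asarray(values, dtype=float)
    edge = 0.5 * (v[0] + v[-1])
    x = np.concatenate(([0.0], np.arange(12) + 0.5, [12.0]))
    y = np.concatenate(([edge], v, [edge]))
    return x, y


def _signed_areas(x: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Exact integrals of max(d, 0) and max(-d, 0) for piecewise-linear d."""
    pos = neg = 0.0
    for i in range(len(x) - 1):
        h = x[i + 1] - x[i]
        a, b = d[i], d[i + 1]
        if a >= 0 and b >= 0:
            pos += 0.5 * (a + b) * h
        elif a <= 0 and b <= 0:
            neg += -0.5 * (a + b) * h
        else:
            # sign change: split at the root of the linear segment
            t = a / (a - b)  # in (0, 1)
            if a > 0:
                pos += 0.5 * a * t * h
                neg += -0.5 * b * (1 - t) * h
            else:
                neg += -0.5 * a * t * h
                pos += 0.5 * b * (1 - t) * h
    return pos, neg


def wlai(prec, temp, sqt: bool = True) -> float:
    """Annual aridity index of one (seasonal) year.

    Parameters
    ----------
    prec, temp : array-like, length 12
        Monthly cumulative precipitation (mm) and monthly mean
        temperature (degC), in seasonal order.
    sqt : bool
        Return the square root of the index (variance-stabilised).

    Returns
    -------
    float
        dry/wet area ratio (or its square root); ``nan`` when the wet
        area is zero (fully arid year, ratio undefined).
    """
    prec = np.asarray(prec, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if prec.shape != (12,) or temp.shape != (12,):
        raise ValueError(
            f"wlai needs exactly 12 monthly values, got {prec.shape}/{temp.shape}"
        )
    if not (np.all(np.isfinite(prec)) and np.all(np.isfinite(temp))):
        raise ValueError("non-finite monthly climate values")
    x, p = _breakpoints(prec)
    _, e = _breakpoints(EVAPORATION_PER_DEGC * temp)
    dry, wet = _signed_areas(x, e - p)
    if wet <= 0.0:
        warnings.warn(
            "wet area is zero: aridity index undefined, returning nan",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    ai = dry / wet
    return float(np.sqrt(ai)) if sqt else float(ai)


def wl_curves(prec, temp) -> pd.DataFrame:
    """Breakpoints of the two diagram curves (for export or plotting)."""
    prec = np.asarray(prec, dtype=float)
    temp = np.asarray(temp, dtype=float)
    x, p = _breakpoints(prec)
    _, e = _breakpoints(EVAPORATION_PER_DEGC * temp)
    return pd.DataFrame({"x": x, "prec": p, "evap": e})


def aridity_table(
    climate: HierSeries, sqt: bool = True
) -> HierSeries:
    """Aridity index per (factor path, year) of a monthly climate series.

    Expects 12 records per (plot, year) in seasonal order, as produced
    by :func:`mldendro.onelevel.move_yr`; years with an undefined index
    are dropped with a warning.
    """
    from .onelevel import wlai_routine

    return wlai_routine(climate, sqt=sqt)
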