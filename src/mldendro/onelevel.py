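"""One-level processing routines and their recursive evaluator.

Ring-width series are prepared for multilevel detrending by a short
chain of routines, each evaluated independently inside every level of a
chosen classification factor:

* :func:`rtimes` - relative-time synchronisation of core replicates,
* :func:`scacum` - cumulative sums, optionally anchored on a reference
  radius (truncated cores miss their innermost rings),
* :func:`amod`   - recursive allometric transformation ``y = a * x**b``
  of the cumulative series (radius -> diameter -> DBH over bark, basal
  area, biomass, ...),
* :func:`move_yr` - seasonal-year relabelling of monthly climate records,
* ``wlai``      - annual aridity index (see :mod:`mldendro.aridity`).

:func:`recursive_eval` applies a named chain of such routines
group-by-group, matching vector-valued arguments (e.g. per-tree
reference radii) to groups by their hierarchy code.
"""

from __future__ import annotations

import inspect
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hierdata import (
    MONTH_ABBREVS,
    _MONTH_TO_NUM,
    HierSeries,
    RadiusVector,
    join_code,
)
from . import aridity as _aridity

__all__ = [
    "rtimes",
    "scacum",
    "amod",
    "move_yr",
    "wlai_routine",
    "recursive_eval",
    "register_routine",
    "ROUTINES",
]


def _group_cols(series: HierSeries, lv: str) -> list[str]:
    """Columns defining evaluation groups: ``lv`` plus every factor above it."""
    if lv not in series.factor_cols:
        raise ValueError(
            f"evaluation level {lv!r} is not a factor column {series.factor_cols}"
        )
    i = series.factor_cols.index(lv)
    return list(series.factor_cols[i:])


def _full_code(keys, cols: Sequence[str]) -> str:
    if not isinstance(keys, tuple):
        keys = (keys,)
    # cols are ordered innermost-first; codes are written outermost-first
    return join_code(str(k) for k in reversed(keys))


# ---------------------------------------------------------------------------


def rtimes(series: HierSeries, lv: str = "tree", only_dup: bool = True) -> HierSeries:
    """Add a relative ``time`` column and synchronise core replicates.

    Within every level of ``lv``, ``time = year - min(year) + 1`` (the
    minimum pooled over the whole group).  When ``only_dup`` and the
    group holds several replicate series, records whose time occurs in a
    single replicate are dropped, so subsequent detrending only sees
    years observed in at least two replicates.  If all times are unique
    (one replicate, no overlap to enforce) the filter is skipped.
    """
    if series.data.empty:
        raise ValueError("empty series")
    gcols = _group_cols(series, lv)
    rep_cols = list(series.factor_cols)
    out = []
    for _, grp in series.data.groupby(gcols, sort=False):
        grp = grp.copy()
        grp["time"] = grp["year"] - int(grp["year"].min()) + 1
        if only_dup:
            counts = grp.groupby("time")[rep_cols].apply(
                lambda g: g.drop_duplicates().shape[0]
            )
            if (counts > 1).any():
                keep = counts.index[counts > 1]
                grp = grp[grp["time"].isin(keep)]
        out.append(grp)
    data = pd.concat(out, ignore_index=True)
    time_cols = series.time_cols
    if "time" not in time_cols:
        time_cols = ("time", *time_cols)
    return series.copy_with(data, time_cols=time_cols)


def _lookup_vector(arg, code: str, what: str) -> float | None:
    if arg is None:
        return None
    if isinstance(arg, RadiusVector):
        val = arg.lookup(code)
        if val is None:
            raise ValueError(f"no {what} entry matches series {code!r}")
        return val
    if isinstance(arg, Mapping):
        parts = code.split(".")
        for k in range(len(parts), 0, -1):
            key = ".".join(parts[:k])
            if key in arg:
                return float(arg[key])
        raise ValueError(f"no {what} entry matches series {code!r}")
    return float(arg)


def scacum(
    series: HierSeries,
    lv: str = "sample",
    sc_c=None,
    rf_t: int | None = None,
) -> HierSeries:
    """Cumulative sums of increments, optionally anchored on a reference.

    Per series (innermost level), ``csx`` is the running sum of ``x``
    ordered by year.  With a scaling constant ``sc_c`` (scalar, mapping
    keyed by hierarchy code, or :class:`RadiusVector`) the whole series
    is shifted by a constant so that ``csx`` equals ``sc_c`` at the
    reference year ``rf_t`` (default: the last year of the series, or
    the measurement year of a :class:`RadiusVector`).  The additive
    shift leaves the increments ``diff(csx) == x`` untouched: a missing
    inner portion of a core is modelled as a constant missing radius.
    """
    gcols = _group_cols(series, lv)
    if rf_t is None and isinstance(sc_c, RadiusVector):
        rf_t = sc_c.year
    out = []
    for keys, grp in series.data.groupby(gcols, sort=False):
        grp = grp.sort_values("year", kind="mergesort").copy()
        csx = grp["x"].cumsum().to_numpy(float)
        code = _full_code(keys, gcols)
        const = _lookup_vector(sc_c, code, "scaling constant")
        if const is not None:
            if const <= 0:
                raise ValueError(f"scaling constant for {code!r} must be positive")
            years = grp["year"].to_numpy()
            ref = int(rf_t) if rf_t is not None else int(years.max())
            hit = np.nonzero(years == ref)[0]
            if hit.size == 0:
                raise ValueError(
                    f"reference time {ref} outside the year range of {code!r} "
                    f"({years.min()}..{years.max()})"
                )
            csx = csx + (const - csx[hit[0]])
        grp["csx"] = csx
        out.append(grp)
    return series.copy_with(pd.concat(out, ignore_index=True))


def amod(
    series: HierSeries,
    lv: str = "sample",
    mp: Sequence[float] = (1.0, 1.0),
    to_cm: bool = False,
) -> HierSeries:
    """Recursive allometric transformation of the cumulative series.

    ``mp = (a1, b1, ..., an, bn)`` applies ``y <- a_i * y**b_i`` in
    order to ``csx`` (``(1, 1)`` keeps radii, ``(2, 1)`` gives
    diameters, ``(0.25*pi, 2)`` basal areas; a second pair can chain a
    fitted DBH-over-bark or biomass equation).  With ``to_cm`` the input
    is converted from mm to cm first.  Increments ``x`` are recomputed
    as successive differences of the transformed cumulative series (the
    first increment equals the first transformed value), so relative and
    cumulative growth live on the same scale.
    """
    mp = np.asarray(mp, dtype=float)
    if mp.size == 0 or mp.size % 2 != 0:
        raise ValueError("mp must be a flat (a1,b1,...,an,bn) sequence of even length")
    if not np.all(np.isfinite(mp)):
        raise ValueError("allometric parameters must be finite")
    if "csx" not in series.data.columns:
        raise ValueError("amod requires the csx column (run scacum first)")
    gcols = _group_cols(series, lv)
    out = []
    for keys, grp in series.data.groupby(gcols, sort=False):
        grp = grp.sort_values("year", kind="mergesort").copy()
        y = grp["csx"].to_numpy(float)
        if to_cm:
            y = y / 10.0
        for a, b in mp.reshape(-1, 2):
            if b != 1.0 and np.any(y <= 0):
                raise ValueError(
                    f"non-positive cumulative value under exponent b={b} in "
                    f"series {_full_code(keys, gcols)!r}"
                )
            y = a * np.power(y, b)
        grp["csx"] = y
        grp["x"] = np.diff(y, prepend=0.0)
        out.append(grp)
    return series.copy_with(pd.concat(out, ignore_index=True))


def _month_number(ini_mnt) -> int:
    if isinstance(ini_mnt, str):
        if ini_mnt not in _MONTH_TO_NUM:
            raise ValueError(
                f"unknown month {ini_mnt!r}; expected one of {MONTH_ABBREVS}"
            )
        return _MONTH_TO_NUM[ini_mnt]
    m = int(ini_mnt)
    if not 1 <= m <= 12:
        raise ValueError(f"initial month {ini_mnt!r} must lie in 1..12")
    return m


def move_yr(series: HierSeries, lv: str = "year", ini_mnt="Oct") -> HierSeries:
    """Relabel monthly records with seasonal years starting at ``ini_mnt``.

    Months at or after the initial month are assigned to the next
    calendar year, so the seasonal year Oct(y-1)..Sep(y) carries the
    label y (October starts the meteorological year in Spain).  Months
    are reordered within each seasonal year starting at ``ini_mnt``, and
    incomplete seasonal years (fewer than 12 months) at the edges of the
    record are dropped.
    """
    ini = _month_number(ini_mnt)
    if "month" not in series.data.columns:
        raise ValueError("move_yr requires a month column")
    df = series.data.copy()
    if ini != 1:
        df["year"] = df["year"] + (df["month"] >= ini).astype(int)
    df["_order"] = (df["month"] - ini) % 12
    df = df.sort_values(
        [*reversed(series.factor_cols), "year", "_order"], kind="mergesort"
    )
    sizes = df.groupby([*series.factor_cols, "year"])["month"].transform("size")
    df = df[sizes == 12].drop(columns="_order")
    return series.copy_with(df)


def wlai_routine(
    series: HierSeries, lv: str = "year", sqt: bool = True
) -> HierSeries:
    """Annual aridity index per (factor path, year) from monthly climate.

    Wraps :func:`mldendro.aridity.wlai`; expects 12 monthly records per
    group in seasonal order (as produced by :func:`move_yr`).
    """
    for col in ("prec", "temp"):
        if col not in series.data.columns:
            raise ValueError(f"wlai requires the {col!r} column")
    gcols = [*series.factor_cols, "year"]
    rows = []
    for keys, grp in series.data.groupby(gcols, sort=False):
        ai = _aridity.wlai(
            grp["prec"].to_numpy(float), grp["temp"].to_numpy(float), sqt=sqt
        )
        rows.append((*keys, ai))
    out = pd.DataFrame(rows, columns=[*gcols, "AI"]).dropna(subset=["AI"])
    return HierSeries(
        out[["AI", "year", *series.factor_cols]],
        value_cols=("AI",),
        time_cols=("year",),
        factor_cols=series.factor_cols,
    ).sort()


# ---------------------------------------------------------------------------

ROUTINES: dict[str, Callable] = {
    "rtimes": rtimes,
    "scacum": scacum,
    "amod": amod,
    "moveYr": move_yr,
    "move_yr": move_yr,
    "wlai": wlai_routine,
}


def register_routine(name: str, fn: Callable) -> None:
    """Register a user routine ``fn(series, lv, **kwargs) -> HierSeries``."""
    ROUTINES[name] = fn


def recursive_eval(
    series: HierSeries,
    fns: Sequence[str | Callable] = (),
    lvs: Sequence[str] = (),
    **kwargs,
) -> HierSeries:
    """Apply a chain of one-level routines, each at its evaluation level.

    ``fns`` names routines from the registry (or passes callables);
    ``lvs`` gives the matching evaluation level for each.  Remaining
    keyword arguments are forwarded to the routines that accept them, so
    one call can configure the whole chain (e.g. ``sc_c=radii,
    rf_t=2003, mp=(2, 1), only_dup=False``).
    """
    if len(fns) != len(lvs):
        raise ValueError(
            f"fns (len {len(fns)}) and lvs (len {len(lvs)}) must match"
        )
    out = series
    for fn, lv in zip(fns, lvs):
        if callable(fn):
            func = fn
        else:
            try:
                func = ROUTINES[fn]
            except KeyError:
                raise ValueError(
                    f"unknown routine {fn!r}; registered: {sorted(ROUTINES)}"
                ) from None
        accepted = set(inspect.signature(func).parameters)
        extra = {k: v for k, v in kwargs.items() if k in accepted}
        out = func(out, lv=lv, **extra)
    return out
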