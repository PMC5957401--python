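"""Hierarchical dendroclimatic data series.

Field observations of tree growth and climate come as wide tables whose
column headers are dot-separated codes encoding the sampling hierarchy
(e.g. ``"P16106.17.a"`` = plot.tree.core), or as long tables with the
measurements and time units first and the classification factors after,
ordered from the innermost level (core) to the outermost (plot).  This
module parses, validates and reshapes both dialects into one canonical
long representation, :class:`HierSeries`, used by every downstream step.

Conventions for the plain-text (CSV) exchange of these tables: a header
row is required, wide tables carry the calendar years in their first
column, the decimal mark is ``"."`` and an empty cell means missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTH_ABBREVS",
    "HierSeries",
    "RadiusVector",
    "split_code",
    "join_code",
    "default_level_names",
    "parse_wide_growth",
    "parse_wide_climate",
    "parse_long_growth",
    "read_wide_csv",
    "read_long_csv",
    "write_long_csv",
    "to_wide_growth",
]

#: Three-letter English month abbreviations in calendar order.
MONTH_ABBREVS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

_MONTH_TO_NUM = {m: i + 1 for i, m in enumerate(MONTH_ABBREVS)}


def split_code(code: str) -> tuple[str, ...]:
    """Split a dot-separated hierarchy code into its level tokens.

    Tokens are ordered as written: outermost level first.  Empty tokens
    (leading, trailing or doubled dots) are rejected.
    """
    parts = tuple(str(code).split("."))
    if any(p == "" for p in parts):
        raise ValueError(f"malformed hierarchy code {code!r}: empty level token")
    return parts


def join_code(levels: Iterable[str]) -> str:
    """Inverse of :func:`split_code`: dot-join level tokens."""
    parts = [str(p) for p in levels]
    if any("." in p or p == "" for p in parts):
        raise ValueError(f"level tokens {parts!r} must be non-empty and dot-free")
    return ".".join(parts)


def default_level_names(n_fields: int) -> tuple[str, ...]:
    """Default level names for a code with ``n_fields`` dot-fields.

    Three fields follow the plot.tree.sample convention of ring-width
    chronologies; a single field is a plot code (climate tables).
    """
    if n_fields == 3:
        return ("plot", "tree", "sample")
    if n_fields == 1:
        return ("plot",)
    return tuple(f"level{i + 1}" for i in range(n_fields))


@dataclass
class HierSeries:
    """Canonical long table of hierarchically grouped time series.

    Parameters
    ----------
    data : pandas.DataFrame
        Long table holding the value column(s), then time columns, then
        factor columns.
    value_cols : sequence of str
        Names of the numeric measurement columns (e.g. ``["x"]`` for
        ring widths, ``["prec", "temp"]`` for climate).
    time_cols : sequence of str
        Time-unit columns ordered lower unit first (``["month", "year"]``
        or ``["year"]``).  Years are integers; months are 1..12.
    factor_cols : sequence of str
        Classification factors ordered innermost level first
        (e.g. ``["sample", "tree", "plot"]``).
    """

    data: pd.DataFrame
    value_cols: tuple[str, ...]
    time_cols: tuple[str, ...]
    factor_cols: tuple[str, ...]

    def __post_init__(self) -> None:
        self.value_cols = tuple(self.value_cols)
        self.time_cols = tuple(self.time_cols)
        self.factor_cols = tuple(self.factor_cols)
        cols = [*self.value_cols, *self.time_cols, *self.factor_cols]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns {missing} not present in data")
        extra = [c for c in self.data.columns if c not in cols]
        self.data = self.data[cols + extra].reset_index(drop=True)
        for c in self.factor_cols:
            self.data[c] = self.data[c].astype(str)
        if "year" in self.time_cols:
            self.data["year"] = self.data["year"].astype(int)
        if "month" in self.time_cols:
            self.data["month"] = self.data["month"].astype(int)
            bad = ~self.data["month"].between(1, 12)
            if bad.any():
                raise ValueError("month values must lie in 1..12")
        self.validate_unique()

    # -- structural helpers -------------------------------------------------

    @property
    def key_cols(self) -> list[str]:
        return [*self.factor_cols, *self.time_cols]

    def validate_unique(self) -> None:
        dup = self.data.duplicated(subset=self.key_cols)
        if dup.any():
            row = self.data.loc[dup.idxmax(), self.key_cols].to_dict()
            raise ValueError(f"duplicate (factors, time) key: {row}")

    def codes(self) -> pd.Series:
        """Dot-joined full hierarchy code per record, outermost level first."""
        parts = [self.data[c] for c in reversed(self.factor_cols)]
        out = parts[0].astype(str)
        for p in parts[1:]:
            out = out + "." + p.astype(str)
        return out

    def copy_with(self, data: pd.DataFrame, **kwargs) -> "HierSeries":
        fields = dict(
            value_cols=self.value_cols,
            time_cols=self.time_cols,
            factor_cols=self.factor_cols,
        )
        fields.update(kwargs)
        return HierSeries(data.reset_index(drop=True), **fields)

    def sort(self) -> "HierSeries":
        cols = [*reversed(self.factor_cols), *reversed(self.time_cols)]
        return self.copy_with(self.data.sort_values(cols, kind="mergesort"))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.data)


@dataclass
class RadiusVector:
    """Reference radii measured at a known year, keyed by tree-level code.

    Core samples often miss the innermost rings, so the cumulative sum of
    ring widths underestimates the stem radius; an externally measured
    radius (mm) at a known calendar year anchors the cumulative series.
    """

    entries: dict[str, float]
    year: int

    def __post_init__(self) -> None:
        self.entries = {str(k): float(v) for k, v in self.entries.items()}
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("reference radii must be strictly positive")
        self.year = int(self.year)

    def lookup(self, code: str) -> float | None:
        """Match ``code`` or any outer prefix of it (cores inherit the
        radius of their tree)."""
        parts = split_code(code)
        for k in range(len(parts), 0, -1):
            key = ".".join(parts[:k])
            if key in self.entries:
                return self.entries[key]
        return None


# -- parsers ----------------------------------------------------------------


def _check_headers(headers: Sequence[str], n_fields: int | None = None) -> int:
    if len(set(headers)) != len(headers):
        dup = [h for h in headers if list(headers).count(h) > 1]
        raise ValueError(f"duplicate column headers: {sorted(set(dup))}")
    counts = {h: len(split_code(h)) for h in headers}
    uniq = set(counts.values())
    if len(uniq) > 1:
        raise ValueError(
            "inconsistent dot-field counts across headers: "
            + ", ".join(f"{h!r}({n})" for h, n in counts.items())
        )
    found = uniq.pop()
    if n_fields is not None and found != n_fields:
        raise ValueError(
            f"headers have {found} dot-fields but {n_fields} level names given"
        )
    return found


def _year_index(table: pd.DataFrame) -> pd.Index:
    try:
        return table.index.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row labels must be integer years: {exc}") from None


def parse_wide_growth(
    table: pd.DataFrame,
    level_names: Sequence[str] | None = None,
    value_col: str = "x",
) -> HierSeries:
    """Parse a wide growth table (years in rows, dot-coded series in columns).

    Each non-missing cell becomes one long record; the split header
    populates the factor columns, innermost level first in the output.
    """
    headers = list(table.columns)
    if not headers:
        raise ValueError("wide growth table has no series columns")
    n_fields = _check_headers(headers)
    if level_names is None:
        level_names = default_level_names(n_fields)
    else:
        level_names = tuple(level_names)
        _check_headers(headers, len(level_names))
    years = _year_index(table)

    frames = []
    for h in headers:
        vals = pd.to_numeric(table[h], errors="coerce")
        keep = vals.notna().to_numpy()
        if not keep.any():
            continue
        rec = pd.DataFrame({value_col: vals.to_numpy()[keep], "year": years[keep]})
        for name, tok in zip(level_names, split_code(h)):
            rec[name] = tok
        frames.append(rec)
    if not frames:
        raise ValueError("wide growth table contains no non-missing cells")
    long = pd.concat(frames, ignore_index=True)
    return HierSeries(
        long,
        value_cols=(value_col,),
        time_cols=("year",),
        factor_cols=tuple(reversed(level_names)),
    ).sort()


def parse_wide_climate(
    prec_table: pd.DataFrame,
    temp_table: pd.DataFrame,
    level_name: str = "plot",
) -> HierSeries:
    """Parse paired wide climate tables with ``plot.Mon`` headers.

    Joins monthly cumulative precipitation (mm) and monthly mean
    temperature (degC) on (plot, year, month); only plots and years
    present in both tables are kept.
    """

    def melt(table: pd.DataFrame, value: str) -> pd.DataFrame:
        _check_headers(list(table.columns), 2)
        years = _year_index(table)
        frames = []
        for h in table.columns:
            plot, mon = split_code(h)
            if mon not in _MONTH_TO_NUM:
                raise ValueError(
                    f"header {h!r}: unknown month token {mon!r} "
                    f"(expected one of {MONTH_ABBREVS})"
                )
            vals = pd.to_numeric(table[h], errors="coerce")
            keep = vals.notna().to_numpy()
            frames.append(
                pd.DataFrame(
                    {
                        value: vals.to_numpy()[keep],
                        "month": _MONTH_TO_NUM[mon],
                        "year": years[keep],
                        level_name: plot,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    prec = melt(prec_table, "prec")
    temp = melt(temp_table, "temp")
    joined = prec.merge(temp, on=["month", "year", level_name], how="inner")
    if joined.empty:
        raise ValueError("precipitation and temperature tables share no (plot, year)")
    joined = joined[["prec", "temp", "month", "year", level_name]]
    return HierSeries(
        joined,
        value_cols=("prec", "temp"),
        time_cols=("month", "year"),
        factor_cols=(level_name,),
    ).sort()


def parse_long_growth(
    table: pd.DataFrame,
    value_col: str = "x",
    time_cols: Sequence[str] = ("year",),
    factor_cols: Sequence[str] = ("sample", "tree", "plot"),
) -> HierSeries:
    """Parse an already-long growth table (factors innermost to outermost)."""
    return HierSeries(
        table.copy(),
        value_cols=(value_col,),
        time_cols=tuple(time_cols),
        factor_cols=tuple(factor_cols),
    ).sort()


# -- CSV I/O ----------------------------------------------------------------


def read_wide_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide CSV whose first column holds the calendar years."""
    df = pd.read_csv(path, index_col=0)
    df.index = _year_index(df)
    return df


def read_long_csv(
    path: str | Path,
    value_cols: Sequence[str],
    time_cols: Sequence[str],
    factor_cols: Sequence[str],
) -> HierSeries:
    df = pd.read_csv(
        path, dtype={c: str for c in factor_cols}, keep_default_na=True
    )
    return HierSeries(
        df,
        value_cols=tuple(value_cols),
        time_cols=tuple(time_cols),
        factor_cols=tuple(factor_cols),
    ).sort()


def write_long_csv(series: HierSeries, path: str | Path) -> None:
    series.data.to_csv(path, index=False)


def to_wide_growth(series: HierSeries, value_col: str | None = None) -> pd.DataFrame:
    """Pivot a canonical growth series back to the wide dialect."""
    value_col = value_col or series.value_cols[0]
    df = series.data.copy()
    df["_code"] = series.codes()
    wide = df.pivot(index="year", columns="_code", values=value_col)
    wide.index.name = None
    wide.columns.name = None
    return wide
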