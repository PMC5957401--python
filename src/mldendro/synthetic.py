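"""Seeded generators of synthetic growth and climate fixtures.

The generators emulate the structure of the study design every module
is exercised on: a small network of permanent plots (two by default),
two trees per plot and two increment cores per tree, with ring widths
spanning roughly 125 years, plus monthly climate records per plot and a
short vector of reference tree radii.

Ring widths are generated on the log-increment scale, so the
multilevel time-decline detrending model *is* the data-generating
process: per core, ``log(x_t) = A + B*log(csx_t) - C*f(t) + e_t`` with
``A, B, C`` the fixed coefficients plus nested plot/tree/core random
effects, ``csx_t`` the concurrent cumulative growth (the implicit
per-year equation is solved by fixed-point iteration, unique for
``B < 1``), and ``e_t`` white or ARMA noise.  Climate is a sinusoidal
seasonal cycle per plot with optional linear trends and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .hierdata import (
    MONTH_ABBREVS,
    HierSeries,
    RadiusVector,
    parse_long_growth,
)

__all__ = ["SimDesign", "gen_growth", "gen_climate"]


@dataclass(frozen=True)
class SimDesign:
    """Design and parameters of the synthetic dendroclimatic study.

    Growth side: ``beta = (b0, b1, b2)`` of the log-linear time-decline
    model (logarithmic form by default), random-effect SDs per level
    (plot, tree, core) for the intercept, the log-cumulative slope and
    the time slope, and the residual SD on the log scale.  The defaults
    give 125-year cores with early ring widths near 2 mm declining to
    below 1 mm and final radii around 15-20 cm.

    Climate side: monthly mean temperature (degC) and monthly
    precipitation (mm) as seasonal sinusoids (warm dry summer, cool wet
    winter) with per-plot offsets, optional linear annual trends and
    observation noise.
    """

    n_plots: int = 2
    n_trees: int = 2
    n_cores: int = 2
    years: tuple[int, int] = (1881, 2005)

    beta: tuple[float, float, float] = (0.6, 0.5, 0.7)
    log_t: bool = True
    sd_intercept: tuple[float, float, float] = (0.25, 0.2, 0.05)
    sd_logcsx: tuple[float, float, float] = (0.02, 0.02, 0.005)
    sd_time: tuple[float, float, float] = (0.08, 0.08, 0.02)
    sigma: float = 0.3
    arma: tuple[float, float] | None = None  # (phi, theta) on the log scale
    truncate_max: int = 0  # max missing inner rings per core

    temp_mean: float = 11.0
    temp_amplitude: float = 8.0
    temp_trend: float = 0.0  # degC / year
    temp_noise: float = 1.0
    temp_plot_sd: float = 1.0
    prec_mean: float = 45.0
    prec_amplitude: float = 25.0
    prec_trend: float = 0.0  # mm / year
    prec_noise: float = 12.0
    prec_plot_sd: float = 8.0

    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] + 1 < 10:
            raise ValueError("year range must span at least 10 years")
        sds = (*self.sd_intercept, *self.sd_logcsx, *self.sd_time, self.sigma)
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if self.arma is not None and abs(self.arma[0]) >= 1:
            raise ValueError("autoregressive parameter must satisfy |phi| < 1")


def _plot_codes(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def _noise(rng, n, design: SimDesign) -> np.ndarray:
    """Residual series on the log scale: white or ARMA(1,1) innovations."""
    if design.sigma == 0:
        return np.zeros(n)
    a = rng.normal(0.0, design.sigma, size=n + 1)
    if design.arma is None:
        return a[1:]
    phi, theta = design.arma
    eps = np.empty(n + 1)
    eps[0] = a[0] / np.sqrt(max(1e-12, 1 - phi**2))
    for t in range(1, n + 1):
        eps[t] = phi * eps[t - 1] + theta * a[t - 1] + a[t]
    return eps[1:]


def _solve_increment(A: float, B: float, C_ft: float, eps: float, cum: float) -> float:
    """Solve ``log(x) = A + B*log(cum + x) - C_ft + eps`` for ``x > 0``.

    With ``cum = 0`` the equation is an exact power law; otherwise the
    fixed-point map contracts whenever ``B * x / (cum + x) < 1`` and a
    few dozen iterations reach machine precision.
    """
    rhs0 = A - C_ft + eps
    if cum <= 0:
        if B >= 1:
            raise ValueError(
                "the first-ring equation has no stable solution for B >= 1"
            )
        return float(np.exp(rhs0 / (1 - B)))
    u = np.log(max(cum * 0.02, 1e-8))
    for _ in range(200):
        u_new = rhs0 + B * np.log(cum + np.exp(u))
        if abs(u_new - u) < 1e-13:
            u = u_new
            break
        u = u_new
    x = float(np.exp(u))
    if not np.isfinite(x):
        raise ValueError("non-finite growth increment generated")
    return x


def gen_growth(design: SimDesign) -> tuple[HierSeries, RadiusVector]:
    """Generate ring-width series and matching reference radii.

    Returns the canonical long growth series (value ``x`` in mm, time
    ``year``, factors sample/tree/plot) and a :class:`RadiusVector`
    with one entry per tree (the largest of its cores' final cumulative
    growth, measured in the final year).  With ``truncate_max > 0``, a
    random number of inner rings is dropped per core, emulating cores
    that missed the pith; the radii still refer to the full stem.
    """
    rng = np.random.default_rng(design.seed)
    y0, y1 = design.years
    years = np.arange(y0, y1 + 1)
    n_years = years.size
    f = np.log(np.arange(1, n_years + 1)) if design.log_t else np.arange(1, n_years + 1)
    b0, b1, b2 = design.beta

    rows = []
    radii: dict[str, float] = {}
    for ip, plot in enumerate(_plot_codes(design.n_plots)):
        u_plot = rng.normal(
            0.0,
            [design.sd_intercept[0], design.sd_logcsx[0], design.sd_time[0]],
        )
        for it in range(design.n_trees):
            tree = str(it + 1)
            u_tree = rng.normal(
                0.0,
                [design.sd_intercept[1], design.sd_logcsx[1], design.sd_time[1]],
            )
            finals = []
            for ic in range(design.n_cores):
                core = chr(ord("a") + ic)
                u_core = rng.normal(
                    0.0,
                    [design.sd_intercept[2], design.sd_logcsx[2], design.sd_time[2]],
                )
                A = b0 + u_plot[0] + u_tree[0] + u_core[0]
                B = b1 + u_plot[1] + u_tree[1] + u_core[1]
                C = b2 + u_plot[2] + u_tree[2] + u_core[2]
                eps = _noise(rng, n_years, design)
                cum = 0.0
                xs = np.empty(n_years)
                for t in range(n_years):
                    x = _solve_increment(A, B, C * f[t], eps[t], cum)
                    cum += x
                    xs[t] = x
                finals.append(cum)
                drop = (
                    int(rng.integers(0, design.truncate_max + 1))
                    if design.truncate_max
                    else 0
                )
                for t in range(drop, n_years):
                    rows.append((xs[t], years[t], core, tree, plot))
            # the stem radius is at least any single core's cumulative
            # growth (cores miss rings, never add them)
            radii[f"{plot}.{tree}"] = float(np.max(finals))
    data = pd.DataFrame(rows, columns=["x", "year", "sample", "tree", "plot"])
    series = parse_long_growth(data)
    return series, RadiusVector(radii, year=int(y1))


def gen_growth_frame(design: SimDesign) -> pd.DataFrame:
    """Generate a detrending model frame with exogenous covariates.

    This is the regression twin of the time-decline model, used to
    validate the estimator itself: the cumulative-growth covariate
    ``csx`` follows the *noiseless* population skeleton (the dynamic
    recursion at the fixed coefficients, identical for every core, so
    the design is balanced and the covariates carry no residual noise),
    while the response ``log(x)`` receives the nested plot/tree/core
    random effects and the residual (white or ARMA) noise.  Unlike
    :func:`gen_growth`, the emitted increments are therefore *not* the
    differences of ``csx``: recomputing cumulative sums from the noisy
    increments would feed the current year's noise back into the
    covariate and bias any estimator, whereas this frame is an exactly
    specified mixed model.

    Returns a long DataFrame with columns x, csx, time, year, sample,
    tree, plot, ready for :class:`mldendro.lmm.NestedLMM`.
    """
    rng = np.random.default_rng(design.seed)
    y0, y1 = design.years
    years = np.arange(y0, y1 + 1)
    n_years = years.size
    f = np.log(np.arange(1, n_years + 1)) if design.log_t else np.arange(1, n_years + 1)
    b0, b1, b2 = design.beta
    # population skeleton of cumulative growth (no noise, fixed coefficients)
    cum = 0.0
    csx = np.empty(n_years)
    for t in range(n_years):
        x = _solve_increment(b0, b1, b2 * f[t], 0.0, cum)
        cum += x
        csx[t] = cum
    log_csx = np.log(csx)

    rows = []
    for plot in _plot_codes(design.n_plots):
        u_plot = rng.normal(
            0.0, [design.sd_intercept[0], design.sd_logcsx[0], design.sd_time[0]]
        )
        for it in range(design.n_trees):
            tree = str(it + 1)
            u_tree = rng.normal(
                0.0, [design.sd_intercept[1], design.sd_logcsx[1], design.sd_time[1]]
            )
            for ic in range(design.n_cores):
                core = chr(ord("a") + ic)
                u_core = rng.normal(
                    0.0,
                    [design.sd_intercept[2], design.sd_logcsx[2], design.sd_time[2]],
                )
                A = b0 + u_plot[0] + u_tree[0] + u_core[0]
                B = b1 + u_plot[1] + u_tree[1] + u_core[1]
                C = b2 + u_plot[2] + u_tree[2] + u_core[2]
                eps = _noise(rng, n_years, design)
                logx = A + B * log_csx - C * f + eps
                for t in range(n_years):
                    rows.append(
                        (np.exp(logx[t]), csx[t], t + 1, years[t], core, tree, plot)
                    )
    return pd.DataFrame(
        rows, columns=["x", "csx", "time", "year", "sample", "tree", "plot"]
    )


def gen_climate(design: SimDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate wide monthly precipitation and temperature tables.

    One column per (plot, month abbreviation); rows are the design's
    years.  Temperature peaks in July, precipitation dips in July (a
    Mediterranean regime); per-plot offsets, linear annual trends and
    white observation noise are added, and precipitation is truncated
    at zero.
    """
    rng = np.random.default_rng(
        None if design.seed is None else design.seed + 1_000_003
    )
    y0, y1 = design.years
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    season = np.cos(2 * np.pi * (months - 7) / 12.0)  # +1 in July
    prec_cols = {}
    temp_cols = {}
    for plot in _plot_codes(design.n_plots):
        t_off = rng.normal(0.0, design.temp_plot_sd)
        p_off = rng.normal(0.0, design.prec_plot_sd)
        for m, mon in zip(months, MONTH_ABBREVS):
            t_clim = design.temp_mean + t_off + design.temp_amplitude * season[m - 1]
            p_clim = design.prec_mean + p_off - design.prec_amplitude * season[m - 1]
            t_series = (
                t_clim
                + design.temp_trend * (years - y0)
                + rng.normal(0.0, design.temp_noise, size=years.size)
            )
            p_series = (
                p_clim
                + design.prec_trend * (years - y0)
                + rng.normal(0.0, design.prec_noise, size=years.size)
            )
            temp_cols[f"{plot}.{mon}"] = t_series
            prec_cols[f"{plot}.{mon}"] = np.maximum(p_series, 0.0)
    index = pd.Index(years)
    return (
        pd.DataFrame(prec_cols, index=index),
        pd.DataFrame(temp_cols, index=index),
    )
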