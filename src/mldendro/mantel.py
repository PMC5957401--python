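"""Mantel correlograms between detrended fluctuation series.

Two fluctuation sets sharing an outermost factor (e.g. core-level
ring-width fluctuations and plot-level aridity fluctuations) are
compared through Mantel correlograms: pairwise Euclidean distances
between years of one series are standardised to z-scores, the distances
of the other series are binned into equal-width classes (class count
from the Sturges rule), and within every class the mean standardised
distance r(d) is tested by simultaneous row/column permutation of the
z-matrix.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "sturges_nclass",
    "standardized_dists",
    "distance_classes",
    "mantel_r",
    "mantel_perm",
    "mantel_correlogram",
    "mule_man",
]


def sturges_nclass(m: int) -> int:
    """Number of distance classes for ``m`` pairwise distances:
    ``ceil(1 + 3.3 * log10(m))``."""
    if m < 1:
        raise ValueError(f"need at least one pairwise distance, got {m}")
    return int(np.ceil(1.0 + 3.3 * np.log10(m)))


def standardized_dists(values: Sequence[float]) -> np.ndarray:
    """Condensed upper-triangle z-scores of pairwise absolute differences.

    The Euclidean distances ``|x_i - x_j|`` over all pairs are centred
    and scaled (sample SD) to mean 0, SD 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    d = pdist(x[:, None], metric="euclidean")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series: pairwise distances have zero spread")
    return (d - d.mean()) / sd


def distance_classes(dists: np.ndarray, n_classes: int | None = None) -> tuple[np.ndarray, int]:
    """Equal-width class index per condensed distance.

    Classes partition ``[min, max]`` of the observed distances; the
    maximum falls in the last class.  Returns (class index per pair,
    number of classes).
    """
    d = np.asarray(dists, dtype=float)
    if n_classes is None:
        n_classes = sturges_nclass(d.size)
    lo, hi = d.min(), d.max()
    if hi == lo:
        return np.zeros(d.size, dtype=int), 1
    idx = np.floor((d - lo) / (hi - lo) * n_classes).astype(int)
    return np.minimum(idx, n_classes - 1), n_classes


def mantel_r(z: np.ndarray, class_idx: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class Mantel statistic: mean of z over the pairs in each class.

    Empty classes yield ``nan``.
    """
    z = np.asarray(z, dtype=float)
    class_idx = np.asarray(class_idx)
    counts = np.bincount(class_idx, minlength=n_classes).astype(float)
    sums = np.bincount(class_idx, weights=z, minlength=n_classes)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def mantel_perm(
    z: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    nperm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p-value per distance class.

    The z-matrix is permuted simultaneously by rows and columns
    ``nperm`` times; ``p = (1 + #{|r_perm| >= |r_obs|}) / (nperm + 1)``.
    Returns (r_obs per class, p per class).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    rng = np.random.default_rng(rng)
    z = np.asarray(z, dtype=float)
    m = z.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    Z = squareform(z)
    iu = _pair_index(n)
    r_obs = mantel_r(z, class_idx, n_classes)
    exceed = np.zeros(n_classes)
    for _ in range(nperm):
        p = rng.permutation(n)
        zp = Z[np.ix_(p, p)][iu]
        r_p = mantel_r(zp, class_idx, n_classes)
        with np.errstate(invalid="ignore"):
            exceed += np.abs(r_p) >= np.abs(r_obs)
    pvals = (1.0 + exceed) / (nperm + 1.0)
    pvals = np.where(np.isnan(r_obs), np.nan, pvals)
    return r_obs, pvals


def mantel_correlogram(
    series_z: Sequence[float],
    series_w: Sequence[float],
    nperm: int = 999,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mantel correlogram of one series against another's distance classes.

    ``series_z`` supplies the standardised distances (the statistic),
    ``series_w`` the distances that are binned into classes (the
    membership matrices); both must be aligned on the same years.
    """
    zs = standardized_dists(series_z)
    dw = pdist(np.asarray(series_w, dtype=float)[:, None], metric="euclidean")
    class_idx, n_classes = distance_classes(dw)
    r, p = mantel_perm(zs, class_idx, n_classes, nperm=nperm, rng=rng)
    counts = np.bincount(class_idx, minlength=n_classes)
    lo, hi = dw.min(), dw.max()
    width = (hi - lo) / n_classes if hi > lo else 0.0
    midpoints = lo + (np.arange(n_classes) + 0.5) * width if width else np.array([lo])
    if midpoints.size < n_classes:
        midpoints = np.resize(midpoints, n_classes)
    return pd.DataFrame(
        {
            "class": np.arange(n_classes),
            "midpoint": midpoints,
            "r": r,
            "p": p,
            "n_pairs": counts,
            "significant": p <= alpha,
        }
    )


def mule_man(
    growth_frame,
    climate_frame,
    nperm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multivariate comparison of two model frames via Mantel correlograms.

    For every innermost series of ``growth_frame`` (a core), the
    fluctuations are paired with the ``climate_frame`` fluctuation
    series of the same outermost-factor level (the plot), restricted to
    their common years.  The growth distances supply the standardised
    z-matrix, the climate distances define the classes; per class a
    two-sided permutation p-value is computed.

    Sign convention of a distance-based correlogram: r(d) is the mean
    growth-distance z-score among the pairs of class d, so a positive
    association between the two fluctuation series appears as
    *negative* r in the short-distance classes (years with similar
    aridity show below-average growth distances).
    """
    g_series = growth_frame.fluc_series()
    c_series = climate_frame.fluc_series()
    # climate frames are grouped by the outermost factor only
    c_by_outer = {code.split(".")[0]: s for code, s in c_series.items()}
    shared = {code.split(".")[0] for code in g_series} & set(c_by_outer)
    if not shared:
        raise ValueError(
            "the two frames share no outermost-factor level: "
            f"{sorted({c.split('.')[0] for c in g_series})} vs {sorted(c_by_outer)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for code, gs in g_series.items():
        outer = code.split(".")[0]
        if outer not in c_by_outer:
            continue
        cs = c_by_outer[outer]
        years = gs.index.intersection(cs.index)
        if len(years) < 3:
            raise ValueError(
                f"series {code!r} shares only {len(years)} years with its "
                f"climate series; need at least 3"
            )
        tab = mantel_correlogram(
            gs.loc[years].to_numpy(),
            cs.loc[years].to_numpy(),
            nperm=nperm,
            rng=rng,
            alpha=alpha,
        )
        tab.insert(0, "series", code)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
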