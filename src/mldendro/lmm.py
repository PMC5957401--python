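"""REML estimation of Gaussian linear mixed models with nested grouping.

The detrending models used throughout this package are linear mixed
models with strictly nested grouping levels (e.g. core within tree
within plot), random-effect covariance restricted to a diagonal
(``pdDiag``-style, one SD per covariate per level) or a multiple of the
identity (``pdIdent``-style, one shared SD per level), an optional
stationary ARMA(p, q) within-series error correlation, and an optional
"constant plus power of the fitted value" error variance function.

Writing the marginal covariance of the response for one outermost group
as ``sigma**2 * Sigma(theta)``, the restricted likelihood is profiled
over the fixed effects (GLS) and the residual variance, and maximised
over ``theta`` (variance ratios, ARMA and variance-function parameters)
by quasi-Newton search on unconstrained transforms.  The outermost
groups are independent, so all linear algebra is blocked per group.

The public surface follows the statsmodels convention: a
:class:`NestedLMM` model object is built from a data frame, ``fit()``
returns a :class:`NestedLMMResults` carrying estimates, uncertainties,
diagnostics and ``summary()``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.tsa.arima_process import arma_acf
from statsmodels.tsa.statespace.tools import (
    constrain_stationary_univariate,
    unconstrain_stationary_univariate,
)

__all__ = [
    "RandomStructure",
    "ARMACorrelation",
    "ConstPowerVariance",
    "NestedLMM",
    "NestedLMMResults",
    "ConvergenceWarning",
    "eval_expr",
    "arma_corr",
    "var_const_power",
    "normalize_residuals",
    "acf_resid",
    "info_criteria",
    "lr_test",
]


class ConvergenceWarning(UserWarning):
    pass


# -- tiny expression language ----------------------------------------------

_LOG_RE = re.compile(r"^log\(\s*([A-Za-z_]\w*)\s*\)$")


def eval_expr(expr: str, data: pd.DataFrame) -> np.ndarray:
    """Evaluate a model term: a column name, ``log(column)`` or ``1``."""
    expr = expr.strip()
    if expr in ("1", "(Intercept)"):
        return np.ones(len(data))
    m = _LOG_RE.match(expr)
    if m:
        col = m.group(1)
        if col not in data.columns:
            raise ValueError(f"term {expr!r}: no column {col!r}")
        vals = data[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"term {expr!r}: log of non-positive values")
        return np.log(vals)
    if expr in data.columns:
        return data[expr].to_numpy(dtype=float)
    raise ValueError(f"cannot evaluate model term {expr!r}")


# -- specification objects --------------------------------------------------


@dataclass(frozen=True)
class RandomStructure:
    """Random-effect covariance per grouping level.

    ``kind='diag'`` estimates one standard deviation per covariate per
    level (independent random intercept and slopes); ``kind='ident'``
    estimates a single standard deviation shared by all covariates of a
    level (a multiple of the identity).  ``covariates=None`` defaults to
    the fixed-effects terms (intercept included).
    """

    kind: str = "diag"
    covariates: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("diag", "ident"):
            raise ValueError("random structure kind must be 'diag' or 'ident'")
        if self.covariates is not None:
            object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class ARMACorrelation:
    """Stationary ARMA(p, q) correlation of within-series errors."""

    p: int = 1
    q: int = 1

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.p + self.q == 0:
            raise ValueError("ARMA correlation needs p >= 0, q >= 0, p + q >= 1")


@dataclass(frozen=True)
class ConstPowerVariance:
    """Error SD proportional to ``rho1 + |fitted|**rho2`` per observation."""

    rho1_start: float = 1.0
    rho2_start: float = 0.0


def arma_corr(phi: Sequence[float] = (), theta: Sequence[float] = (), n: int = 1) -> np.ndarray:
    """Toeplitz correlation matrix of a stationary ARMA process.

    ``phi`` are autoregressive coefficients, ``theta`` moving-average
    coefficients; ``n`` is the series length.  With neither, the
    process is white noise and the identity is returned.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float)) if len(np.atleast_1d(phi)) else np.empty(0)
    theta = np.atleast_1d(np.asarray(theta, dtype=float)) if len(np.atleast_1d(theta)) else np.empty(0)
    if phi.size and np.any(np.abs(np.roots(np.r_[1.0, -phi])) >= 1):
        raise ValueError("non-stationary autoregressive parameters")
    if phi.size == 0 and theta.size == 0:
        return np.eye(n)
    rho = arma_acf(np.r_[1.0, -phi], np.r_[1.0, theta], lags=n)
    return linalg.toeplitz(rho)


def var_const_power(rho1: float, rho2: float, fitted: Sequence[float]) -> np.ndarray:
    """Per-observation SD multipliers ``rho1 + |fitted|**rho2``."""
    nu = np.abs(np.asarray(fitted, dtype=float))
    w = rho1 + nu**rho2
    if np.any(w <= 0):
        raise ValueError("variance-function multiplier is not positive")
    return w


# -- model -------------------------------------------------------------------


def _slices_from_keys(keys: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of identical keys (data must be sorted by them)."""
    change = np.nonzero(keys[1:] != keys[:-1])[0] + 1
    starts = np.r_[0, change]
    stops = np.r_[change, len(keys)]
    return list(zip(starts.tolist(), stops.tolist()))


class NestedLMM:
    """Linear mixed model with nested grouping levels.

    Parameters
    ----------
    data : pandas.DataFrame
        Model frame; one row per observation.
    response : str
        Response term, e.g. ``"log(x)"`` or ``"AI"``.
    fixed : sequence of str
        Fixed-effect covariate terms (an intercept is always included),
        e.g. ``["log(csx)", "log(time)"]``.
    groups : sequence of str
        Nested grouping factor columns, outermost first, e.g.
        ``["plot", "tree", "sample"]``.  Empty for ordinary least
        squares.
    random : RandomStructure
        Random-effect covariance applied at every grouping level.
    correlation : ARMACorrelation, optional
        Within-series (innermost-level) error correlation; lags are
        measured on the ``order_col`` column (default ``"year"``).
    variance : ConstPowerVariance, optional
        Const-plus-power variance function on the fitted values.
    method : {"REML", "ML"}
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        fixed: Sequence[str],
        groups: Sequence[str] = (),
        random: RandomStructure | None = None,
        correlation: ARMACorrelation | None = None,
        variance: ConstPowerVariance | None = None,
        method: str = "REML",
        order_col: str = "year",
    ) -> None:
        if method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        self.method = method
        self.response = response
        self.fixed = tuple(fixed)
        self.groups = tuple(groups)
        self.random = random or RandomStructure()
        self.correlation = correlation
        self.variance = variance
        self.order_col = order_col if order_col in data.columns else None

        sort_cols = [*self.groups] + ([self.order_col] if self.order_col else [])
        frame = data.sort_values(sort_cols, kind="mergesort") if sort_cols else data
        self.data = frame.reset_index(drop=True)

        self.y = eval_expr(response, self.data)
        self.exog_names = ["(Intercept)", *self.fixed]
        self.X = np.column_stack(
            [eval_expr(t, self.data) for t in self.exog_names]
        )
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite response or covariates after transforms")
        self.nobs = len(self.y)
        self.p = self.X.shape[1]
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("singular fixed-effects design matrix")

        rcov = self.random.covariates
        if rcov is None:
            rcov = tuple(self.exog_names)
        self.random_names = tuple(rcov)
        self.U = np.column_stack([eval_expr(t, self.data) for t in rcov])
        self.q = self.U.shape[1]
        self.n_sd_per_level = self.q if self.random.kind == "diag" else 1

        # nested group slices per level (data sorted, so runs are contiguous)
        self._level_slices: list[list[tuple[int, int]]] = []
        self.group_labels: list[list[str]] = []
        for i in range(len(self.groups)):
            key = self.data[list(self.groups[: i + 1])].astype(str).agg(".".join, axis=1)
            sl = _slices_from_keys(key.to_numpy())
            self._level_slices.append(sl)
            self.group_labels.append([key.iloc[s] for s, _ in sl])
        self.ngroups = {
            g: len(sl) for g, sl in zip(self.groups, self._level_slices)
        }
        self._outer = self._level_slices[0] if self.groups else [(0, self.nobs)]
        self._inner = self._level_slices[-1] if self.groups else [(0, self.nobs)]
        if self.order_col:
            order = self.data[self.order_col].to_numpy(dtype=float)
        else:
            order = np.arange(self.nobs, dtype=float)
        self._lags = [
            np.abs(order[a:b, None] - order[None, a:b]).astype(int)
            for a, b in self._inner
        ]
        self._max_lag = max(int(l.max()) for l in self._lags) if self._lags else 0

        # parameter layout: [sd ratios per level] + [ar] + [ma] + [variance]
        self.n_levels = len(self.groups)
        self._build_lowrank()
        self._n_sd = self.n_levels * self.n_sd_per_level
        self._n_ar = self.correlation.p if self.correlation else 0
        self._n_ma = self.correlation.q if self.correlation else 0
        self._n_var = 2 if self.variance else 0
        self.n_theta = self._n_sd + self._n_ar + self._n_ma + self._n_var
        self.k_params = self.p + self.n_theta + 1  # + residual sigma

    def _build_lowrank(self) -> None:
        """Per outer group: random-effect design W (block-sparse columns,
        one block of ``q`` columns per subgroup at every level) and, for
        the identity error covariance, cached cross-products."""
        self._W: list[np.ndarray] = []
        self._col_level: list[np.ndarray] = []
        self._g_inner: list[list[int]] = []
        self._cross0: list[tuple] = []
        for gs, ge in self._outer:
            blocks = []  # (level, start, stop, column offset)
            off = 0
            for lvl in range(self.n_levels):
                for ss, se in self._level_slices[lvl]:
                    if ss >= gs and se <= ge:
                        blocks.append((lvl, ss, se, off))
                        off += self.q
            W = np.zeros((ge - gs, off))
            col_level = np.empty(off, dtype=int)
            for lvl, ss, se, o in blocks:
                W[ss - gs : se - gs, o : o + self.q] = self.U[ss:se]
                col_level[o : o + self.q] = lvl
            self._W.append(W)
            self._col_level.append(col_level)
            self._g_inner.append(
                [i for i, (cs, ce) in enumerate(self._inner) if cs >= gs and ce <= ge]
            )
            Xg, yg = self.X[gs:ge], self.y[gs:ge]
            self._cross0.append(
                (
                    W.T @ W,
                    W.T @ Xg,
                    W.T @ yg,
                    Xg.T @ Xg,
                    Xg.T @ yg,
                    float(yg @ yg),
                )
            )

    # -- parameter transforms -----------------------------------------------

    def _unpack(self, theta: np.ndarray):
        i = 0
        sd_ratios = np.exp(theta[i : i + self._n_sd]).reshape(
            self.n_levels, self.n_sd_per_level
        )
        i += self._n_sd
        phi = (
            constrain_stationary_univariate(theta[i : i + self._n_ar])
            if self._n_ar
            else np.empty(0)
        )
        i += self._n_ar
        ma = (
            constrain_stationary_univariate(theta[i : i + self._n_ma])
            if self._n_ma
            else np.empty(0)
        )
        i += self._n_ma
        if self._n_var:
            rho1, rho2 = np.exp(theta[i]), theta[i + 1]
        else:
            rho1 = rho2 = None
        return sd_ratios, phi, ma, rho1, rho2

    def _d2_per_level(self, sd_ratios: np.ndarray) -> np.ndarray:
        if self.random.kind == "ident":
            return np.repeat(sd_ratios, self.q, axis=1) ** 2
        return sd_ratios**2

    # -- likelihood ----------------------------------------------------------

    def _error_corr_blocks(self, phi, ma) -> list[np.ndarray] | None:
        if not self.correlation:
            return None
        try:
            rho = arma_acf(
                np.r_[1.0, -np.atleast_1d(phi)] if len(phi) else np.array([1.0]),
                np.r_[1.0, np.atleast_1d(ma)] if len(ma) else np.array([1.0]),
                lags=self._max_lag + 1,
            )
        except Exception:
            return [None]  # signal failure
        if not np.all(np.isfinite(rho)):
            return [None]
        return [rho[l] for l in self._lags]

    def _evaluate(self, theta: np.ndarray, nu: np.ndarray | None, full: bool = False):
        """Profiled -2 log-likelihood; with ``full`` also beta, sigma, etc."""
        big = 1e10
        sd_ratios, phi, ma, rho1, rho2 = self._unpack(theta)
        d2 = self._d2_per_level(sd_ratios)
        corr_blocks = self._error_corr_blocks(phi, ma)
        if corr_blocks is not None and corr_blocks[0] is None:
            return big if not full else None
        if self._n_var:
            w_all = rho1 + np.abs(nu) ** rho2
            if np.any(w_all <= 0) or not np.all(np.isfinite(w_all)):
                return big if not full else None
        else:
            w_all = None

        need_whiten = corr_blocks is not None or w_all is not None
        logdet = 0.0
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        s_acc = 0.0
        for g_idx, (gs, ge) in enumerate(self._outer):
            if need_whiten:
                # whiten rows by the per-series error Cholesky factors
                Xw = self.X[gs:ge].copy()
                Ww = self._W[g_idx].copy()
                yw = self.y[gs:ge].astype(float).copy()
                for c_idx in self._g_inner[g_idx]:
                    cs, ce = self._inner[c_idx]
                    blk = (
                        corr_blocks[c_idx].copy()
                        if corr_blocks is not None
                        else np.eye(ce - cs)
                    )
                    if w_all is not None:
                        w = w_all[cs:ce]
                        blk *= np.outer(w, w)
                    try:
                        L = np.linalg.cholesky(blk)
                    except np.linalg.LinAlgError:
                        return big if not full else None
                    logdet += 2.0 * np.sum(np.log(np.diag(L)))
                    rows = slice(cs - gs, ce - gs)
                    Xw[rows] = linalg.solve_triangular(L, Xw[rows], lower=True)
                    Ww[rows] = linalg.solve_triangular(L, Ww[rows], lower=True)
                    yw[rows] = linalg.solve_triangular(L, yw[rows], lower=True)
                G = Ww.T @ Ww
                P = Ww.T @ Xw
                qv = Ww.T @ yw
                A0 = Xw.T @ Xw
                b0 = Xw.T @ yw
                s0 = float(yw @ yw)
            else:
                G, P, qv, A0, b0, s0 = self._cross0[g_idx]
            r = G.shape[0]
            if r:
                lvl = self._col_level[g_idx]
                dcol = np.sqrt(d2[lvl, np.arange(r) % self.q])
                M = dcol[:, None] * G * dcol[None, :]
                M[np.diag_indices(r)] += 1.0
                try:
                    cM, lowM = linalg.cho_factor(M, lower=True)
                except linalg.LinAlgError:
                    return big if not full else None
                logdet += 2.0 * np.sum(np.log(np.diag(cM)))
                S = dcol[:, None] * P
                tq = dcol * qv
                Z1 = linalg.cho_solve((cM, lowM), S)
                Z2 = linalg.cho_solve((cM, lowM), tq)
                A += A0 - S.T @ Z1
                b += b0 - S.T @ Z2
                s_acc += s0 - float(tq @ Z2)
            else:
                A += A0
                b += b0
                s_acc += s0
        try:
            cA, low = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return big if not full else None
        beta = linalg.cho_solve((cA, low), b)
        rss = max(s_acc - float(b @ beta), 1e-300)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cA)))
        N, p = self.nobs, self.p
        if self.method == "REML":
            dof = N - p
            sigma2 = rss / dof
            neg2ll = dof * (np.log(2 * np.pi * sigma2) + 1) + logdet + logdet_A
        else:
            dof = N
            sigma2 = rss / N
            neg2ll = N * (np.log(2 * np.pi * sigma2) + 1) + logdet
        if not np.isfinite(neg2ll):
            return big if not full else None
        if not full:
            return neg2ll
        cov_beta = sigma2 * linalg.cho_solve((cA, low), np.eye(p))
        return {
            "neg2ll": neg2ll,
            "beta": beta,
            "sigma2": sigma2,
            "cov_beta": cov_beta,
            "sd_ratios": sd_ratios,
            "phi": np.atleast_1d(phi) if len(np.atleast_1d(phi)) else np.empty(0),
            "theta_ma": np.atleast_1d(ma) if len(np.atleast_1d(ma)) else np.empty(0),
            "rho1": rho1,
            "rho2": rho2,
            "corr_blocks": corr_blocks,
            "w_all": w_all,
        }

    def loglik(self, theta: np.ndarray, nu: np.ndarray | None = None) -> float:
        """Profiled (restricted) log-likelihood at unconstrained ``theta``."""
        if self._n_var and nu is None:
            nu = self._ols_fitted()
        return -0.5 * self._evaluate(np.asarray(theta, dtype=float), nu)

    def _ols_fitted(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        return self.X @ beta

    def _starts(self) -> list[np.ndarray]:
        """Starting points: moment-based SD ratios (per-level spread of
        OLS group-mean residuals over the residual SD), plus coarser
        fallbacks when a correlation structure makes the surface
        multimodal (a group intercept and a strong AR term can trade
        off)."""
        base = np.full(self.n_theta, 0.0)
        base[: self._n_sd] = np.log(0.375)
        resid = self.y - self._ols_fitted()
        s = resid.std()
        moment = base.copy()
        if s > 0 and self.n_levels:
            icpt = (
                self.random_names.index("(Intercept)")
                if "(Intercept)" in self.random_names
                else None
            )
            for lvl in range(self.n_levels):
                means = [resid[a:b].mean() for a, b in self._level_slices[lvl]]
                ratio = float(np.clip(np.std(means) / s, 0.02, 10.0))
                j = lvl * self.n_sd_per_level
                if self.random.kind == "ident" or icpt is None:
                    moment[j] = np.log(ratio)
                else:
                    moment[j + icpt] = np.log(ratio)
        starts = [moment]
        if self._n_ar or self._n_ma:
            with_ar = moment.copy()
            i = self._n_sd
            if self._n_ar:
                with_ar[i : i + self._n_ar] = unconstrain_stationary_univariate(
                    np.r_[0.3, np.zeros(self._n_ar - 1)]
                )
            starts.append(with_ar)
            starts.append(base)
        return starts

    # -- fitting -------------------------------------------------------------

    def fit(self, maxiter: int = 500, tol: float = 1e-10) -> "NestedLMMResults":
        if self.n_theta == 0 and not self.correlation and not self.variance:
            return self._fit_ols()
        nu = self._ols_fitted() if self._n_var else None
        outer_iters = 4 if self._n_var else 1
        starts = self._starts()
        theta = starts[0]
        bounds = [(-15.0, 8.0)] * self._n_sd + [(-8.0, 8.0)] * (
            self._n_ar + self._n_ma
        ) + [(-8.0, 8.0)] * self._n_var
        res = None
        first = True
        for _ in range(outer_iters):
            candidates = starts if first else [theta]
            first = False
            res = None
            for x0 in candidates:
                cand = optimize.minimize(
                    self._evaluate,
                    x0,
                    args=(nu,),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
                )
                if res is None or cand.fun < res.fun:
                    res = cand
            # simplex polish: the log-scale profile is flat near zero
            # variance components and quasi-Newton can stall there
            res2 = optimize.minimize(
                self._evaluate,
                res.x,
                args=(nu,),
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": 3000, "fatol": 1e-10, "xatol": 1e-7},
            )
            converged = bool(res2.success or res.success)
            if res2.fun <= res.fun:
                res = res2
            theta = res.x
            if self._n_var:
                fit = self._evaluate(theta, nu, full=True)
                if fit is None:
                    break
                nu = self._fitted_from(fit)
        if res is not None and not converged:
            warnings.warn(
                f"optimizer did not report convergence ({res.message}); "
                f"last parameter state: {res.x}",
                ConvergenceWarning,
            )
        fit = self._evaluate(theta, nu, full=True)
        if fit is None:
            raise RuntimeError("likelihood not finite at the final parameters")
        return NestedLMMResults(
            self, theta, fit, nu, converged=bool(res is None or converged)
        )

    def _fit_ols(self) -> "NestedLMMResults":
        """Degenerate no-grouping fit: exact least squares.

        Reported with the maximised (ML) Gaussian log-likelihood and
        ``k = p + 1`` parameters, matching the usual linear-model
        conventions, so information criteria are comparable with
        published single-level fits.
        """
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        rss = float(resid @ resid)
        N, p = self.nobs, self.p
        sigma2_ml = rss / N
        neg2ll = N * (np.log(2 * np.pi * sigma2_ml) + 1)
        fit = {
            "neg2ll": neg2ll,
            "beta": beta,
            "sigma2": rss / (N - p),
            "cov_beta": rss / (N - p) * np.linalg.inv(self.X.T @ self.X),
            "sd_ratios": np.empty((0, self.n_sd_per_level)),
            "phi": np.empty(0),
            "theta_ma": np.empty(0),
            "rho1": None,
            "rho2": None,
            "corr_blocks": None,
            "w_all": None,
        }
        return NestedLMMResults(self, np.empty(0), fit, None, converged=True, ols=True)

    def _fitted_from(self, fit: Mapping) -> np.ndarray:
        """Fitted values including BLUP contributions at the innermost level."""
        beta = fit["beta"]
        fitted = self.X @ beta
        if not self.groups:
            return fitted
        blups = self._blups(fit)
        for lvl in range(self.n_levels):
            for j, (ss, se) in enumerate(self._level_slices[lvl]):
                fitted[ss:se] += self.U[ss:se] @ blups[lvl][j]
        return fitted

    def _blups(self, fit: Mapping) -> list[list[np.ndarray]]:
        """Empirical BLUPs of every group's random-effect vector."""
        beta = fit["beta"]
        d2 = self._d2_per_level(fit["sd_ratios"])
        corr_blocks = fit["corr_blocks"]
        w_all = fit["w_all"]
        qvec = np.empty(self.nobs)
        for gs, ge in self._outer:
            n = ge - gs
            Sigma = np.zeros((n, n))
            for c_idx, (cs, ce) in enumerate(self._inner):
                if cs < gs or ce > ge:
                    continue
                blk = (
                    corr_blocks[c_idx] if corr_blocks is not None else np.eye(ce - cs)
                )
                if w_all is not None:
                    w = w_all[cs:ce]
                    blk = blk * np.outer(w, w)
                Sigma[cs - gs : ce - gs, cs - gs : ce - gs] = blk
            for lvl in range(self.n_levels):
                dl = d2[lvl]
                for ss, se in self._level_slices[lvl]:
                    if ss < gs or se > ge:
                        continue
                    Us = self.U[ss:se]
                    Sigma[ss - gs : se - gs, ss - gs : se - gs] += (Us * dl) @ Us.T
            r = self.y[gs:ge] - self.X[gs:ge] @ beta
            qvec[gs:ge] = linalg.cho_solve(linalg.cho_factor(Sigma), r)
        blups = []
        for lvl in range(self.n_levels):
            dl = d2[lvl]
            blups.append(
                [
                    dl * (self.U[ss:se].T @ qvec[ss:se])
                    for ss, se in self._level_slices[lvl]
                ]
            )
        return blups


# -- results -----------------------------------------------------------------


class NestedLMMResults:
    """Fitted nested mixed model: estimates, diagnostics, summary."""

    def __init__(self, model, theta, fit, nu, converged, ols=False):
        self.model = model
        self.method = model.method if not ols else "OLS"
        self.theta = np.asarray(theta, dtype=float)
        self.converged = converged
        self._ols = ols

        self.params = pd.Series(fit["beta"], index=model.exog_names)
        self.cov_params = pd.DataFrame(
            fit["cov_beta"], index=model.exog_names, columns=model.exog_names
        )
        self.bse = pd.Series(np.sqrt(np.diag(fit["cov_beta"])), index=model.exog_names)
        self.sigma2 = float(fit["sigma2"])
        self.sigma = float(np.sqrt(self.sigma2))
        self.llf = -0.5 * float(fit["neg2ll"])
        self.nobs = model.nobs
        self.k_params = (model.p + 1) if ols else model.k_params
        self.ngroups = dict(model.ngroups)

        sd = fit["sd_ratios"] * self.sigma
        self.varcomps: dict[str, pd.Series] = {}
        for lvl, g in enumerate(model.groups):
            if model.random.kind == "ident":
                vals = np.repeat(sd[lvl], model.q)
            else:
                vals = sd[lvl]
            self.varcomps[g] = pd.Series(vals, index=model.random_names)
        self.corr_params = {
            "phi": fit["phi"].copy(),
            "theta": fit["theta_ma"].copy(),
        }
        self.var_params = (
            {"rho1": float(fit["rho1"]), "rho2": float(fit["rho2"])}
            if fit["rho1"] is not None
            else None
        )
        self._fit = fit
        self._nu = nu

        if model.groups and not ols:
            self.blups = model._blups(fit)
            self.fittedvalues = model._fitted_from(fit)
        else:
            self.blups = []
            self.fittedvalues = model.X @ fit["beta"]
        self.resid = model.y - self.fittedvalues
        self.df = self._containment_df()
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df), index=model.exog_names
        )

    # -- information criteria -----------------------------------------------

    @property
    def aic(self) -> float:
        return info_criteria(self.llf, self.k_params, self.nobs, self.model.p, self.method)[0]

    @property
    def bic(self) -> float:
        return info_criteria(self.llf, self.k_params, self.nobs, self.model.p, self.method)[1]

    # -- degrees of freedom ---------------------------------------------------

    def _containment_df(self) -> pd.Series:
        """Containment denominator DF per fixed term.

        Each term is assigned to the outermost level within whose groups
        it is constant; terms varying within the innermost groups (and
        the intercept) belong to the observation level.  The DF of level
        i is ``m_i - m_{i-1} - p_i`` with ``m_i`` the number of groups
        at level i (``m_0 = 1``, observations at the last level) and
        ``p_i`` the number of non-intercept terms assigned to it.
        """
        model = self.model
        Q = model.n_levels
        if Q == 0:
            return pd.Series(
                float(model.nobs - model.p), index=model.exog_names
            )
        m = [1] + [len(sl) for sl in model._level_slices] + [model.nobs]
        levels = {}
        for j, name in enumerate(model.exog_names):
            if name == "(Intercept)":
                levels[name] = Q + 1
                continue
            col = model.X[:, j]
            assigned = Q + 1
            for i in range(Q, 0, -1):
                const = all(
                    np.ptp(col[s:e]) == 0 for s, e in model._level_slices[i - 1]
                )
                if const:
                    assigned = i
                else:
                    break
            levels[name] = assigned
        p_at = {}
        for name, lvl in levels.items():
            if name != "(Intercept)":
                p_at[lvl] = p_at.get(lvl, 0) + 1
        df = {}
        for name, lvl in levels.items():
            df[name] = float(m[lvl] - m[lvl - 1] - p_at.get(lvl, 0))
        return pd.Series(df, index=model.exog_names)

    # -- residual diagnostics --------------------------------------------------

    def resid_by_group(self, normalized: bool = False):
        """Innermost-level residual series: list of (code, years, values)."""
        model = self.model
        resid = self.resid_normalized if normalized else self.resid
        labels = model.group_labels[-1] if model.groups else ["all"]
        out = []
        for lab, (s, e) in zip(labels, model._inner):
            years = (
                model.data[model.order_col].to_numpy()[s:e]
                if model.order_col
                else np.arange(e - s)
            )
            out.append((lab, years, resid[s:e]))
        return out

    @property
    def resid_normalized(self) -> np.ndarray:
        """Residuals whitened by the estimated within-series covariance.

        Per innermost series the raw residuals are premultiplied by the
        inverse Cholesky factor of the estimated error covariance
        ``sigma**2 * W``, so a correctly specified model leaves
        approximately uncorrelated unit-variance series.
        """
        return normalize_residuals(self)

    def acf(self, max_lag: int = 10, alpha: float = 0.05, normalized: bool = True):
        groups = [v for _, _, v in self.resid_by_group(normalized=normalized)]
        return acf_resid(groups, max_lag=max_lag, alpha=alpha)

    # -- presentation -----------------------------------------------------------

    def summary(self) -> str:
        model = self.model
        lines = []
        if self._ols:
            lines.append("Linear model fit by least squares")
        else:
            lines.append(f"Linear mixed-effects model fit by {self.method}")
        lines.append(f"{'AIC':>12} {'BIC':>12} {'logLik':>12}")
        lines.append(f"{self.aic:>12.4f} {self.bic:>12.4f} {self.llf:>12.4f}")
        if self.varcomps:
            lines.append("")
            lines.append("Random effects:")
            rhs = " + ".join(
                t for t in model.random_names if t != "(Intercept)"
            )
            for i, (g, sds) in enumerate(self.varcomps.items()):
                path = " %in% ".join(reversed(list(self.varcomps)[: i + 1]))
                lines.append(f" Formula: ~{rhs} | {path}")
                struct = (
                    "Diagonal" if model.random.kind == "diag" else "Multiple of an Identity"
                )
                lines.append(f" Structure: {struct}")
                names = list(sds.index)
                vals = [f"{v:.6g}" for v in sds]
                if i == len(self.varcomps) - 1:
                    names.append("Residual")
                    vals.append(f"{self.sigma:.6g}")
                lines.append("          " + " ".join(f"{n:>12}" for n in names))
                lines.append("  StdDev: " + " ".join(f"{v:>12}" for v in vals))
        if self.corr_params["phi"].size or self.corr_params["theta"].size:
            lines.append("")
            lines.append(
                "Correlation structure: ARMA"
                f"({self.corr_params['phi'].size},{self.corr_params['theta'].size})"
                f"  phi: {np.round(self.corr_params['phi'], 4)}"
                f"  theta: {np.round(self.corr_params['theta'], 4)}"
            )
        if self.var_params:
            lines.append(
                "Variance function: constant + power of fitted "
                f"(rho1={self.var_params['rho1']:.4g}, rho2={self.var_params['rho2']:.4g})"
            )
        lines.append("")
        lines.append(
            "Fixed effects: "
            f"{model.response} ~ " + " + ".join(model.fixed or ["1"])
        )
        lines.append(
            f"{'':>12} {'Value':>12} {'Std.Error':>12} {'DF':>6} {'t-value':>10} {'p-value':>8}"
        )
        for name in model.exog_names:
            lines.append(
                f"{name:>12} {self.params[name]:>12.6f} {self.bse[name]:>12.7f} "
                f"{int(self.df[name]):>6d} {self.tvalues[name]:>10.6f} "
                f"{self.pvalues[name]:>8.4f}"
            )
        std = self.resid / self.sigma
        qs = np.percentile(std, [0, 25, 50, 75, 100])
        lines.append("")
        lines.append("Standardized Within-Group Residuals:")
        lines.append(
            f"{'Min':>12} {'Q1':>12} {'Med':>12} {'Q3':>12} {'Max':>12}"
        )
        lines.append(" ".join(f"{v:>12.7f}" for v in qs))
        lines.append("")
        lines.append(f"Number of Observations: {self.nobs}")
        if self.ngroups:
            lines.append("Number of Groups:")
            for i, g in enumerate(self.model.groups):
                path = " %in% ".join(reversed(self.model.groups[: i + 1]))
                lines.append(f"  {path}: {self.ngroups[g]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable summary."""
        return {
            "method": self.method,
            "loglik": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "k_params": self.k_params,
            "nobs": self.nobs,
            "sigma": self.sigma,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "df": self.df.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "varcomps": {g: s.to_dict() for g, s in self.varcomps.items()},
            "corr_params": {
                k: v.tolist() for k, v in self.corr_params.items()
            },
            "var_params": self.var_params,
            "ngroups": self.ngroups,
            "converged": self.converged,
        }

    def __repr__(self) -> str:  # pragma: no cover
        return f"<NestedLMMResults llf={self.llf:.4f} k={self.k_params} n={self.nobs}>"


# -- free diagnostics ---------------------------------------------------------


def normalize_residuals(results: NestedLMMResults) -> np.ndarray:
    """Whiten innermost-level residuals with the estimated error covariance.

    For each innermost series the estimated covariance ``sigma**2 * W``
    (ARMA correlation times variance-function weights) is factored
    ``W = L L^T`` and the raw residuals are replaced by
    ``L^{-1} e / sigma``; with ``W = I`` this is just ``e / sigma``.
    """
    model = results.model
    fit = results._fit
    resid = results.resid
    out = np.empty_like(resid)
    corr_blocks = fit["corr_blocks"]
    w_all = fit["w_all"]
    for c_idx, (s, e) in enumerate(model._inner):
        blk = corr_blocks[c_idx] if corr_blocks is not None else None
        if blk is None and w_all is None:
            out[s:e] = resid[s:e] / results.sigma
            continue
        W = blk.copy() if blk is not None else np.eye(e - s)
        if w_all is not None:
            w = w_all[s:e]
            W = W * np.outer(w, w)
        L = np.linalg.cholesky(results.sigma2 * W)
        out[s:e] = linalg.solve_triangular(L, resid[s:e], lower=True)
    return out


def acf_resid(
    groups: Sequence[np.ndarray], max_lag: int = 10, alpha: float = 0.05
) -> pd.DataFrame:
    """Pooled empirical autocorrelation of grouped residual series.

    ``rho(l)`` pools lagged products across all groups, dividing by the
    number of pairs at each lag, and normalises by the pooled lag-0
    term.  The two-sided critical bound at each lag is
    ``z_{1-alpha/2} / sqrt(N(l))``.
    """
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    groups = [np.asarray(g, dtype=float) for g in groups]
    longest = max(len(g) for g in groups)
    if max_lag >= longest:
        raise ValueError(
            f"max_lag {max_lag} must be smaller than the longest group ({longest})"
        )
    rows = []
    n0 = sum(len(g) for g in groups)
    denom = sum(float(g @ g) for g in groups) / n0
    z = stats.norm.ppf(1 - alpha / 2)
    for lag in range(max_lag + 1):
        num = 0.0
        npairs = 0
        for g in groups:
            if len(g) > lag:
                num += float(g[lag:] @ g[: len(g) - lag])
                npairs += len(g) - lag
        rho = (num / npairs) / denom if npairs else np.nan
        bound = z / np.sqrt(npairs) if npairs else np.nan
        rows.append((lag, rho, npairs, bound))
    return pd.DataFrame(rows, columns=["lag", "acf", "n_pairs", "bound"])


def info_criteria(
    llf: float, k: int, nobs: int, p: int, method: str = "REML"
) -> tuple[float, float, float]:
    """(AIC, BIC, logLik) from a fit's log-likelihood and parameter count.

    The BIC sample size is the effective ``nobs - p`` (with ``p`` the
    number of fixed-effect coefficients): the restricted likelihood is
    a likelihood of ``nobs - p`` error contrasts, and mixed-model
    comparison tables conventionally apply the same effective size to
    every model in the table, single-level fits included.
    """
    aic = -2.0 * llf + 2.0 * k
    bic = -2.0 * llf + k * np.log(nobs - p)
    return float(aic), float(bic), float(llf)


def lr_test(big, small) -> tuple[float, int, float]:
    """Likelihood-ratio test of two nested fits.

    Accepts results objects (``llf``/``k_params`` attributes) or
    ``(llf, k)`` tuples; returns (L.Ratio, df, p) with the chi-square
    upper-tail p-value.  Comparing REML fits whose fixed effects differ
    is reported as printed by common software but warned about, since
    restricted likelihoods are not strictly comparable across
    fixed-effect structures.
    """

    def get(obj):
        if hasattr(obj, "llf"):
            return float(obj.llf), int(obj.k_params), obj
        llf, k = obj
        return float(llf), int(k), None

    llf_b, k_b, rb = get(big)
    llf_s, k_s, rs = get(small)
    if k_b <= k_s:
        raise ValueError(f"models are not nested: k_big={k_b} <= k_small={k_s}")
    if rb is not None and rs is not None:
        mb, ms = getattr(rb, "method", None), getattr(rs, "method", None)
        if "REML" in (mb, ms) and mb != ms:
            warnings.warn(
                "comparing a REML fit with a non-REML fit: restricted "
                "likelihoods are not strictly comparable across "
                "fixed-effect structures",
                UserWarning,
            )
    stat = 2.0 * (llf_b - llf_s)
    df = k_b - k_s
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), df, pval
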