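"""Detrending formula builders and the model-frame orchestration.

A *model frame* ties the whole growth- or climate-side pipeline
together: it runs the one-level routines over the hierarchical series,
builds a detrending formula, fits the nested mixed model by REML, and
extracts the within-group fluctuation series (the detrended residuals)
that downstream comparison works on.

Two formula families are provided.  ``td_form`` is the log-linear
growth-theory expression ``log(x) ~ log(csx) + f(t) | plot/tree/sample``
with ``f(t) = t`` (a time-decline, Chapman-Richards-like form) or
``f(t) = log(t)`` (a logarithmic time-decline, Levakovic-like form).
``lme_form`` is the plain linear expression ``resp ~ covar | group``
used to detrend annual aridity indices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierdata import HierSeries, RadiusVector, parse_wide_climate, parse_wide_growth
from .lmm import (
    ARMACorrelation,
    ConstPowerVariance,
    NestedLMM,
    NestedLMMResults,
    RandomStructure,
)
from .onelevel import recursive_eval

__all__ = ["GrowthFormulaSpec", "td_form", "lme_form", "ModelFrame", "model_frame"]

_GROWTH_DEFAULT_FNS = ("rtimes", "scacum", "amod")
_GROWTH_DEFAULT_LVS = ("tree", "sample", "sample")
_CLIMATE_DEFAULT_FNS = ("moveYr", "wlai")
_CLIMATE_DEFAULT_LVS = ("year", "year")


@dataclass(frozen=True)
class GrowthFormulaSpec:
    """Resolved description of a detrending model.

    ``groups`` are the grouping factors actually used, outermost first
    (the data hierarchy minus any removed levels); ``fixed`` holds the
    covariate terms of the fixed part (intercept implied).
    """

    response: str
    fixed: tuple[str, ...]
    groups: tuple[str, ...]
    random: RandomStructure = RandomStructure()
    correlation: ARMACorrelation | None = None
    variance: ConstPowerVariance | None = None
    method: str = "REML"

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        grp = "/".join(self.groups) if self.groups else "1"
        return f"{self.response} ~ {rhs} | {grp}"


def _drop_levels(hierarchy: Sequence[str], lev_rm) -> tuple[str, ...]:
    if lev_rm is None:
        lev_rm = ()
    if isinstance(lev_rm, str):
        lev_rm = (lev_rm,)
    unknown = [l for l in lev_rm if l not in hierarchy]
    if unknown:
        raise ValueError(f"lev_rm names unknown factors {unknown}; have {list(hierarchy)}")
    return tuple(g for g in hierarchy if g not in lev_rm)


def td_form(
    hierarchy: Sequence[str],
    on_time: bool = True,
    log_t: bool = False,
    lev_rm=None,
    **model_opts,
) -> GrowthFormulaSpec:
    """Growth-theory detrending spec ``log(x) ~ log(csx) + f(t) | group``.

    ``hierarchy`` lists the data's factors outermost first (e.g.
    ``("plot", "tree", "sample")``).  ``on_time`` selects relative time
    over calendar year; ``log_t`` selects the logarithmic time-decline
    form.  ``lev_rm`` removes factors from the grouping term.
    """
    t = "time" if on_time else "year"
    f_t = f"log({t})" if log_t else t
    return GrowthFormulaSpec(
        response="log(x)",
        fixed=("log(csx)", f_t),
        groups=_drop_levels(hierarchy, lev_rm),
        **model_opts,
    )


def lme_form(
    data: HierSeries,
    resp: str | None = None,
    covar: str | None = None,
    lev_rm=None,
    **model_opts,
) -> GrowthFormulaSpec:
    """Plain linear detrending spec ``resp ~ covar | group``.

    Defaults: the response is the first value column of ``data`` and
    the covariate its first time column ordered year-outward (for an
    aridity table, ``AI ~ year | plot``).
    """
    if resp is None:
        resp = data.value_cols[0]
    elif resp not in data.data.columns:
        raise ValueError(f"unknown response column {resp!r}")
    if covar is None:
        covar = data.time_cols[-1]
    else:
        for c in covar.split("+"):
            if c.strip() not in data.data.columns:
                raise ValueError(f"unknown covariate column {c.strip()!r}")
    hierarchy = tuple(reversed(data.factor_cols))
    return GrowthFormulaSpec(
        response=resp,
        fixed=tuple(c.strip() for c in covar.split("+")),
        groups=_drop_levels(hierarchy, lev_rm),
        **model_opts,
    )


def _as_correlation(corr) -> ARMACorrelation | None:
    if corr is None or isinstance(corr, ARMACorrelation):
        return corr
    p, q = corr
    return ARMACorrelation(int(p), int(q))


def _as_random(random) -> RandomStructure:
    if random is None:
        return RandomStructure()
    if isinstance(random, RandomStructure):
        return random
    return RandomStructure(kind=str(random))


class ModelFrame:
    """Processed series, fitted detrending model and fluctuation table.

    Attributes
    ----------
    model : NestedLMMResults
        The fitted nested mixed model.
    fluc : pandas.DataFrame
        One detrended fluctuation per observation: the full factor
        path, the year, and the within-group residual, ordered by year
        inside each innermost series.
    call : dict
        Fully resolved arguments of the producing call; ``update``
        re-runs the pipeline with selected arguments overridden.
    """

    def __init__(self, model: NestedLMMResults, processed: HierSeries,
                 spec: GrowthFormulaSpec, call: dict):
        self.model = model
        self.processed = processed
        self.spec = spec
        self.call = call
        self.fluc = self.fluctuations(call.get("res_type", "raw"))

    # -- fluctuations --------------------------------------------------------

    def fluctuations(self, res_type: str = "raw") -> pd.DataFrame:
        """Within-group residual series (``raw`` or ``normalized``)."""
        if res_type not in ("raw", "normalized"):
            raise ValueError("res_type must be 'raw' or 'normalized'")
        res = self.model
        resid = res.resid_normalized if res_type == "normalized" else res.resid
        cols = [*self.processed.factor_cols, "year"]
        out = res.model.data[[c for c in cols if c in res.model.data.columns]].copy()
        out["fluc"] = resid
        return out.reset_index(drop=True)

    def fluc_series(self, res_type: str | None = None) -> dict[str, pd.Series]:
        """Fluctuations as {full series code: series indexed by year}."""
        res = self.model
        resid = (
            self.fluctuations(res_type)["fluc"].to_numpy()
            if res_type is not None
            else self.fluc["fluc"].to_numpy()
        )
        out = {}
        labels = res.model.group_labels[-1] if res.model.groups else ["all"]
        years = res.model.data["year"].to_numpy()
        for lab, (s, e) in zip(labels, res.model._inner):
            out[lab] = pd.Series(resid[s:e], index=years[s:e]).sort_index()
        return out

    @property
    def outer_factor(self) -> str:
        return self.spec.groups[0]

    # -- conveniences --------------------------------------------------------

    def summary(self) -> str:
        return self.model.summary()

    def acf(self, max_lag: int = 10, alpha: float = 0.05, res_type: str = "normalized"):
        return self.model.acf(max_lag=max_lag, alpha=alpha,
                              normalized=res_type == "normalized")

    def get_data(self) -> pd.DataFrame:
        """The model frame the detrending model was fitted to."""
        return self.model.model.data.copy()

    def update(self, **changed) -> "ModelFrame":
        """Re-run the pipeline with selected arguments overridden."""
        unknown = [k for k in changed if k not in self.call]
        if unknown:
            raise ValueError(
                f"unknown arguments {unknown}; known: {sorted(self.call)}"
            )
        args = {**self.call, **changed}
        return model_frame(**args)

    def plot(self, ax=None):
        """Minimal fluctuation plot, one line per innermost series."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for code, series in self.fluc_series().items():
            ax.plot(series.index, series.to_numpy(), label=code, lw=0.8)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("year")
        ax.set_ylabel("fluctuation")
        ax.legend(fontsize="x-small")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ModelFrame {self.spec.formula()!r} n={self.model.nobs}>"


def model_frame(
    rd,
    fns: Sequence[str] | None = None,
    lvs: Sequence[str] | None = None,
    form: str | GrowthFormulaSpec = None,
    *,
    # routine arguments
    only_dup: bool = True,
    sc_c=None,
    rf_t: int | None = None,
    mp: Sequence[float] = (1.0, 1.0),
    to_cm: bool = False,
    ini_mnt="Oct",
    sqt: bool = True,
    # formula arguments
    on_time: bool = True,
    log_t: bool = False,
    lev_rm=None,
    resp: str | None = None,
    covar: str | None = None,
    # model arguments
    random=None,
    correlation=None,
    variance=None,
    method: str = "REML",
    res_type: str = "raw",
) -> ModelFrame:
    """Process a hierarchical series, fit the detrending model, extract
    fluctuations.

    ``rd`` is either a growth input (wide table or :class:`HierSeries`)
    or a climate input (a ``(prec, temp)`` pair of wide tables, or an
    already-joined climate :class:`HierSeries`).  Growth inputs default
    to the ``rtimes``/``scacum``/``amod`` chain at tree/sample/sample
    and the ``td_form`` formula; climate inputs default to
    ``moveYr``/``wlai`` at the year level and the ``lme_form`` formula.
    All arguments are recorded, fully resolved, in the returned frame's
    ``call`` so that ``update`` is deterministic.
    """
    climate = False
    if isinstance(rd, (tuple, list)):
        if len(rd) != 2:
            raise ValueError("climate input must be a (prec, temp) pair")
        prec, temp = rd
        series = parse_wide_climate(prec, temp) if isinstance(prec, pd.DataFrame) else rd
        if isinstance(series, (tuple, list)):
            raise ValueError("climate pair must hold wide DataFrames")
        climate = True
    elif isinstance(rd, HierSeries):
        series = rd
        climate = "prec" in series.data.columns and "temp" in series.data.columns
    elif isinstance(rd, pd.DataFrame):
        series = parse_wide_growth(rd)
    else:
        raise TypeError(f"unsupported input type {type(rd).__name__}")

    if fns is None:
        fns = _CLIMATE_DEFAULT_FNS if climate else _GROWTH_DEFAULT_FNS
    if lvs is None:
        lvs = _CLIMATE_DEFAULT_LVS if climate else _GROWTH_DEFAULT_LVS
    if len(fns) != len(lvs):
        raise ValueError(f"fns (len {len(fns)}) and lvs (len {len(lvs)}) must match")
    if form is None:
        form = "lmeForm" if climate else "tdForm"

    processed = recursive_eval(
        series,
        fns,
        lvs,
        only_dup=only_dup,
        sc_c=sc_c,
        rf_t=rf_t,
        mp=mp,
        to_cm=to_cm,
        ini_mnt=ini_mnt,
        sqt=sqt,
    )

    model_opts = dict(
        random=_as_random(random),
        correlation=_as_correlation(correlation),
        variance=variance,
        method=method,
    )
    if isinstance(form, GrowthFormulaSpec):
        spec = form
    elif form == "tdForm":
        hierarchy = tuple(reversed(processed.factor_cols))
        spec = td_form(hierarchy, on_time=on_time, log_t=log_t, lev_rm=lev_rm,
                       **model_opts)
    elif form == "lmeForm":
        spec = lme_form(processed, resp=resp, covar=covar, lev_rm=lev_rm,
                        **model_opts)
    else:
        raise ValueError(f"unknown formula method {form!r}")

    model = NestedLMM(
        processed.data,
        response=spec.response,
        fixed=spec.fixed,
        groups=spec.groups,
        random=spec.random,
        correlation=spec.correlation,
        variance=spec.variance,
        method=spec.method,
    ).fit()

    call = dict(
        rd=series,
        fns=tuple(fns),
        lvs=tuple(lvs),
        form=form,
        only_dup=only_dup,
        sc_c=sc_c,
        rf_t=rf_t,
        mp=tuple(np.atleast_1d(mp).tolist()),
        to_cm=to_cm,
        ini_mnt=ini_mnt,
        sqt=sqt,
        on_time=on_time,
        log_t=log_t,
        lev_rm=lev_rm,
        resp=resp,
        covar=covar,
        random=model_opts["random"],
        correlation=model_opts["correlation"],
        variance=variance,
        method=method,
        res_type=res_type,
    )
    return ModelFrame(model, processed, spec, call)
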