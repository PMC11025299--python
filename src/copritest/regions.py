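"""Rectangular comparison and confidence regions.

Both flavors are one-sided rectangles ``(lb_se, 1] x (lb_sp, 1]`` per test.
The *comparison* region is dual to the multiplicity-adjusted test: it is
contained in the region of interest ``R = {se > se0, sp > sp0}`` exactly
when the test rejects, so its Bonferroni adjustment is ``alpha/m``.  The
*confidence* region must cover all 2m unknown parameters jointly and uses
``alpha/(2m)`` (Bonferroni) or the corresponding 2m-dimensional quantile,
making it strictly more conservative: ``D_alpha`` is a subset of
``C_alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.special import ndtr, ndtri

from ._mvn import equicoordinate_quantile, repair_correlation
from .core import (
    AccuracyEstimate,
    HypothesisSpec,
    StudyData,
    estimate_accuracy,
    wald_statistics,
)
from .mcp import (
    MBetaConfig,
    McpResult,
    UnsupportedProcedureError,
    _indicator_correlation,
    bootstrap_critical_value,
    fit_procedure,
    mbeta_decide,
)


@dataclass(frozen=True)
class RegionSet:
    """Per-test one-sided rectangles with upper limits fixed at 1."""

    flavor: str  # "comparison" | "confidence"
    procedure: str
    lb_se: np.ndarray
    lb_sp: np.ndarray
    alpha_star: float
    diagnostics: dict[str, Any] | None = None

    @property
    def m(self) -> int:
        return self.lb_se.shape[0]


def rectangle_region(est: AccuracyEstimate, n0: int, n1: int,
                     c_star: float) -> tuple[np.ndarray, np.ndarray]:
    """Wald lower bounds ``p_hat - c_star * sqrt(p_hat (1-p_hat)/n)``, clamped at 0."""
    if c_star < 0:
        raise ValueError("c_star must be non-negative")
    lb_se = est.se_hat - c_star * np.sqrt(est.se_hat * (1 - est.se_hat) / n1)
    lb_sp = est.sp_hat - c_star * np.sqrt(est.sp_hat * (1 - est.sp_hat) / n0)
    return np.clip(lb_se, 0.0, None), np.clip(lb_sp, 0.0, None)


def _fit(data, hyp, procedure, result, kw) -> McpResult:
    if result is not None:
        return result
    return fit_procedure(data, hyp, procedure, **kw)


def comparison_regions(data: StudyData, hyp: HypothesisSpec, procedure: str = "maxt",
                       result: McpResult | None = None, shrinkage: float = 0.5,
                       **fit_kw) -> RegionSet:
    """Multiplicity-adjusted comparison regions.

    Containment in the region of interest reproduces the procedure's test
    decision exactly: the rectangle reuses the procedure's m-dimensional
    critical value (Bonferroni: the ``1 - alpha/m`` normal quantile).
    """
    est = estimate_accuracy(data, shrinkage)
    res = _fit(data, hyp, procedure, result, dict(shrinkage=shrinkage, **fit_kw))
    if procedure == "mbeta":
        d = res.diagnostics
        return RegionSet("comparison", "mbeta", d["lower_bound_se"],
                         d["lower_bound_sp"], alpha_star=d["gamma"],
                         diagnostics={"gamma": d["gamma"]})
    if procedure == "none":
        c_star = float(ndtri(1 - hyp.alpha))
    elif procedure == "bonferroni":
        c_star = float(ndtri(1 - hyp.alpha / data.m))
    else:  # maxt / pairs / wild reuse their joint critical value
        c_star = res.critical_value
    lb_se, lb_sp = rectangle_region(est, data.n0, data.n1, max(c_star, 0.0))
    return RegionSet("comparison", procedure, lb_se, lb_sp,
                     alpha_star=float(1 - ndtr(c_star)),
                     diagnostics={"c_star": c_star})


def confidence_regions(data: StudyData, hyp: HypothesisSpec, procedure: str = "maxt",
                       result: McpResult | None = None, shrinkage: float = 0.5,
                       seed: int = 0, **fit_kw) -> RegionSet:
    """Simultaneous one-sided confidence regions covering all 2m parameters."""
    est = estimate_accuracy(data, shrinkage)
    m = data.m
    if procedure == "mbeta":
        cfg = fit_kw.pop("mbeta_cfg", None) or MBetaConfig()
        # full coverage of all 2m parameters == no LFC alteration
        cover_cfg = MBetaConfig(prior_a=cfg.prior_a, prior_b=cfg.prior_b,
                                lfc_pr=0.0, posterior_draws=cfg.posterior_draws)
        res = mbeta_decide(data, hyp, cover_cfg, seed)
        d = res.diagnostics
        return RegionSet("confidence", "mbeta", d["lower_bound_se"],
                         d["lower_bound_sp"], alpha_star=d["gamma"],
                         diagnostics={"gamma": d["gamma"]})
    if procedure == "none":
        c_star = float(ndtri(1 - hyp.alpha / 2))
    elif procedure == "bonferroni":
        c_star = float(ndtri(1 - hyp.alpha / (2 * m)))
    elif procedure == "maxt":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_se = _indicator_correlation(data.correct_cases().astype(float))
            r_sp = _indicator_correlation(data.correct_controls().astype(float))
        full = np.zeros((2 * m, 2 * m))
        full[:m, :m] = r_se
        full[m:, m:] = r_sp
        c_star = equicoordinate_quantile(repair_correlation(full), hyp.alpha, seed=seed)
    elif procedure in ("pairs", "wild"):
        res = _fit(data, hyp, procedure, result, dict(shrinkage=shrinkage, seed=seed, **fit_kw))
        draws = res.diagnostics["draws"]
        c_star = bootstrap_critical_value(draws.max_all, hyp.alpha)
    else:
        raise UnsupportedProcedureError(f"unknown procedure {procedure!r}")
    lb_se, lb_sp = rectangle_region(est, data.n0, data.n1, max(c_star, 0.0))
    return RegionSet("confidence", procedure, lb_se, lb_sp,
                     alpha_star=float(1 - ndtr(c_star)),
                     diagnostics={"c_star": c_star})


def region_test(region_set: RegionSet, hyp: HypothesisSpec) -> np.ndarray:
    """1 iff the rectangle lies inside the open region {se > se0, sp > sp0}."""
    return ((region_set.lb_se > hyp.se0) & (region_set.lb_sp > hyp.sp0)).astype(int)


def plot_regions(region_set: RegionSet, hyp: HypothesisSpec, est: AccuracyEstimate,
                 ax=None, labels=None):
    """Optional one-panel visualization (solid = rejected, dashed = retained)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    dec = region_test(region_set, hyp)
    ax.axvspan(hyp.sp0, 1, ymin=hyp.se0, alpha=0.15, color="green")
    for j in range(region_set.m):
        style = "-" if dec[j] else "--"
        color = "tab:blue" if dec[j] else "tab:orange"
        sp_lo, se_lo = region_set.lb_sp[j], region_set.lb_se[j]
        ax.plot([sp_lo, sp_lo, 1], [1, se_lo, se_lo], style, color=color)
        ax.plot(est.sp_hat[j], est.se_hat[j], "o", color=color)
        if labels is not None:
            ax.annotate(labels[j], (est.sp_hat[j], est.se_hat[j]))
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{region_set.flavor} regions ({region_set.procedure})")
    return ax
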