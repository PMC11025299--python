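"""Multiple comparison procedures for the co-primary hypothesis system.

Each procedure supplies a critical value for the per-test decision rule
``reject test j iff min(Z_j^se, Z_j^sp) > c``:

* ``none``        — unadjusted normal quantile ``z_{1-alpha}``
* ``bonferroni``  — ``z_{1-alpha/m}`` (divisor m, not 2m: only one endpoint
  per test can be at its null boundary under the intersection-union rule)
* ``maxt``        — equicoordinate quantile of an m-variate normal with the
  correlation of the binding test statistics, estimated at the most likely
  least-favourable parameter configuration
* ``pairs``       — subject-level (stratified) bootstrap of the maximum
  statistic
* ``wild``        — residual bootstrap with random weights
* ``mbeta``       — Bayesian multivariate beta-binomial decision rule
  (simultaneous posterior lower bounds; no adjusted p-values)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import beta as beta_dist

from ._mvn import equicoordinate_quantile, mvn_orthant_prob, repair_correlation
from .core import (
    AccuracyEstimate,
    HypothesisSpec,
    InvalidDataError,
    StudyData,
    TestStatistics,
    decide,
    estimate_accuracy,
    wald_statistics,
)

PROCEDURES = ("none", "bonferroni", "maxt", "pairs", "wild", "mbeta")


class UnsupportedProcedureError(ValueError):
    pass


@dataclass(frozen=True)
class LfcCorrelation:
    """Correlation matrix of the binding test statistics."""

    matrix: np.ndarray
    binding_endpoint: np.ndarray

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class BootstrapDraws:
    """Resampled maximum statistics from one bootstrap run.

    ``max_stats`` holds max_j min(Z*_se, Z*_sp) per replicate (the quantity
    calibrating the test / comparison regions); ``max_all`` holds the
    maximum over all 2m centered statistics (calibrating confidence
    regions).
    """

    max_stats: np.ndarray
    max_all: np.ndarray
    B: int
    seed: int
    scheme: str


@dataclass(frozen=True)
class MBetaConfig:
    prior_a: float = 1.0
    prior_b: float = 1.0
    lfc_pr: float = 1.0
    posterior_draws: int = 10_000

    def __post_init__(self):
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if not 0.0 <= self.lfc_pr <= 1.0:
            raise ValueError(f"lfc_pr must lie in [0, 1], got {self.lfc_pr}")
        if self.posterior_draws < 1000:
            warnings.warn("posterior_draws < 1000 gives unstable bounds", stacklevel=2)


@dataclass(frozen=True)
class McpResult:
    procedure: str
    critical_value: float
    decisions: np.ndarray
    adjusted_p: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)


# ----------------------------------------------------------------- parametric

def critical_value_none(alpha: float) -> float:
    """1 - alpha standard-normal quantile (no multiplicity adjustment)."""
    return float(ndtri(1 - alpha))


def critical_value_bonferroni(alpha: float, m: int) -> float:
    """1 - alpha/m standard-normal quantile."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(ndtri(1 - alpha / m))


def _indicator_correlation(cols: np.ndarray) -> np.ndarray:
    """Pearson correlation of binary indicator columns; constant columns -> 0."""
    m = cols.shape[1]
    sd = cols.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn("constant indicator column: correlation set to 0", stacklevel=3)
    safe = np.where(const, 1.0, sd)
    centered = (cols - cols.mean(axis=0)) / safe
    r = (centered.T @ centered) / cols.shape[0]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def estimate_lfc_correlation(data: StudyData, stats: TestStatistics) -> LfcCorrelation:
    """Correlation of the binding statistics at the estimated LFC.

    For each test the binding endpoint (the one attaining ``min(Z_se,
    Z_sp)``) selects the subgroup whose correct-decision indicators drive
    the statistic.  Pairs of tests binding in the same subgroup get the
    empirical indicator correlation; pairs binding in different subgroups
    are independent samples and get 0.
    """
    q1 = data.correct_cases().astype(float)
    q0 = data.correct_controls().astype(float)
    binding = stats.binding_endpoint
    m = data.m
    r = np.zeros((m, m))
    for grp, q in (("se", q1), ("sp", q0)):
        idx = np.flatnonzero(binding == grp)
        if idx.size:
            r[np.ix_(idx, idx)] = _indicator_correlation(q[:, idx])
    np.fill_diagonal(r, 1.0)
    return LfcCorrelation(matrix=repair_correlation(r), binding_endpoint=binding)


def critical_value_maxt(r_hat: LfcCorrelation | np.ndarray, alpha: float,
                        rng_seed: int = 0, tol: float = 1e-3,
                        n_points: int = 8192) -> float:
    """Equicoordinate 1 - alpha quantile of N(0, R_hat)."""
    mat = r_hat.matrix if isinstance(r_hat, LfcCorrelation) else np.asarray(r_hat, float)
    return equicoordinate_quantile(mat, alpha, tol=tol, n_points=n_points, seed=rng_seed)


# ------------------------------------------------------------------ bootstrap

def bootstrap_critical_value(max_stats: np.ndarray, alpha: float) -> float:
    """Order statistic of rank ceil((1-alpha) B) of the resampled maxima."""
    b = len(max_stats)
    rank = int(np.ceil((1 - alpha) * b))
    return float(np.sort(max_stats)[rank - 1])


def _check_bootstrap_pre(data: StudyData, B: int) -> None:
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    if data.n1 < 2 or data.n0 < 2:
        raise InvalidDataError("bootstrap needs at least 2 subjects per subgroup")


def _centered_stats(p_star: np.ndarray, p_hat: np.ndarray, n: int) -> np.ndarray:
    sd = np.sqrt(p_star * (1 - p_star) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p_star - p_hat) / sd
    # 0/0 (replicate equals a degenerate original estimate, h = 0) -> 0
    return np.where((p_star == p_hat) & (sd == 0), 0.0, z)


def _lfc_offsets(est: AccuracyEstimate, hyp: HypothesisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Margins of each endpoint statistic over the per-test binding minimum.

    The bootstrap approximates the null distribution of max_j min(Z_se,
    Z_sp) at the *estimated least-favourable configuration*: per test only
    the binding endpoint sits at its boundary, the other lies further
    inside the alternative by the observed margin.  Adding these offsets
    to the centered replicate statistics reproduces that configuration
    (the binding endpoint gets offset 0); without them the minimum of two
    independently centered statistics would systematically undershoot the
    null distribution.

    Degenerate estimates (exactly 0 or 1, possible with h = 0) get an
    infinite statistic of the matching sign; a test whose statistics are
    both non-finite gets zero offsets.
    """
    def z(p_hat, p0, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (p_hat - p0) / np.sqrt(p_hat * (1 - p_hat) / n)
        return np.where(p_hat >= 1, np.inf, np.where(p_hat <= 0, -np.inf, out))

    z_se = z(est.se_hat, hyp.se0, est.n1)
    z_sp = z(est.sp_hat, hyp.sp0, est.n0)
    z_min = np.minimum(z_se, z_sp)
    with np.errstate(invalid="ignore"):
        off_se = z_se - z_min
        off_sp = z_sp - z_min
    return (np.nan_to_num(off_se, nan=0.0, posinf=np.inf, neginf=0.0),
            np.nan_to_num(off_sp, nan=0.0, posinf=np.inf, neginf=0.0))


def pairs_bootstrap(data: StudyData, est: AccuracyEstimate, hyp: HypothesisSpec,
                    B: int = 2000, seed: int = 0) -> tuple[BootstrapDraws, float]:
    """Stratified subject resampling of whole rows (D, T_1..T_m).

    Subjects are resampled with replacement within their disease group so
    every replicate keeps exactly n1 cases and n0 controls; resampling
    whole rows replicates the between-test correlation.  Replicate
    statistics are centered at the original estimates and the critical
    value is the (1-alpha) order statistic of max_j min(Z*_se, Z*_sp).
    """
    _check_bootstrap_pre(data, B)
    rng = np.random.default_rng(seed)
    h = est.shrinkage
    n1, n0 = data.n1, data.n0
    # multinomial weights over subjects == counts of a with-replacement resample
    w1 = rng.multinomial(n1, np.full(n1, 1.0 / n1), size=B)
    w0 = rng.multinomial(n0, np.full(n0, 1.0 / n0), size=B)
    n11_star = w1 @ data.cases()
    n00_star = w0 @ data.correct_controls()
    se_star = (n11_star + h) / (n1 + 2 * h)
    sp_star = (n00_star + h) / (n0 + 2 * h)
    z_se = _centered_stats(se_star, est.se_hat, n1)
    z_sp = _centered_stats(sp_star, est.sp_hat, n0)
    off_se, off_sp = _lfc_offsets(est, hyp)
    max_stats = np.minimum(z_se + off_se, z_sp + off_sp).max(axis=1)
    max_all = np.maximum(z_se, z_sp).max(axis=1)
    draws = BootstrapDraws(max_stats=max_stats, max_all=max_all, B=B, seed=seed,
                           scheme="pairs")
    return draws, bootstrap_critical_value(max_stats, hyp.alpha)


def _weight_sampler(weight_dist: str | Callable) -> Callable:
    if callable(weight_dist):
        return weight_dist
    if weight_dist == "normal":
        return lambda rng, size: rng.standard_normal(size)
    if weight_dist == "rademacher":
        return lambda rng, size: rng.integers(0, 2, size=size) * 2.0 - 1.0
    if weight_dist == "zero":
        return lambda rng, size: np.zeros(size)
    raise ValueError(f"unknown weight distribution {weight_dist!r}")


def wild_bootstrap(data: StudyData, est: AccuracyEstimate, hyp: HypothesisSpec,
                   B: int = 2000, seed: int = 0,
                   weight_dist: str | Callable = "normal") -> tuple[BootstrapDraws, float]:
    """Residual bootstrap with per-subject random weights.

    Residuals of the correct-decision indicators (relative to the raw
    subgroup means) are resampled with replacement within each subgroup
    and multiplied by one weight per drawn subject, shared across the m
    tests to preserve between-test correlation.  The perturbed values are
    no longer binary, so standard errors come from the original (shrunk)
    estimates.
    """
    _check_bootstrap_pre(data, B)
    rng = np.random.default_rng(seed)
    sample_w = _weight_sampler(weight_dist)
    n1, n0 = data.n1, data.n0
    out = []
    for q, n in ((data.cases().astype(float), n1),
                 (data.correct_controls().astype(float), n0)):
        resid = q - q.mean(axis=0)
        idx = rng.integers(0, n, size=(B, n))
        w = sample_w(rng, (B, n))
        # mean perturbation per replicate and test
        pert = np.einsum("bi,bij->bj", w, resid[idx]) / n
        out.append(pert)
    pert_se, pert_sp = out
    se_std = np.sqrt(est.se_hat * (1 - est.se_hat) / n1)
    sp_std = np.sqrt(est.sp_hat * (1 - est.sp_hat) / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_se = pert_se / se_std
        z_sp = pert_sp / sp_std
    z_se = np.where((se_std == 0) & (pert_se == 0), 0.0, z_se)
    z_sp = np.where((sp_std == 0) & (pert_sp == 0), 0.0, z_sp)
    off_se, off_sp = _lfc_offsets(est, hyp)
    max_stats = np.minimum(z_se + off_se, z_sp + off_sp).max(axis=1)
    max_all = np.maximum(z_se, z_sp).max(axis=1)
    draws = BootstrapDraws(max_stats=max_stats, max_all=max_all, B=B, seed=seed,
                           scheme="wild")
    return draws, bootstrap_critical_value(max_stats, hyp.alpha)


# ---------------------------------------------------------------------- mbeta

def _joint_posterior_uniforms(data: StudyData, cfg: MBetaConfig,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-copula posterior draws on the uniform scale.

    Returns (U, a_post, b_post) where U has one column per parameter in
    the order (se_1..se_m, sp_1..sp_m) and the marginal posterior of
    parameter k is Beta(a_post[k], b_post[k]).
    """
    m = data.m
    x_se = data.cases().sum(axis=0)
    x_sp = data.correct_controls().sum(axis=0)
    a_post = np.concatenate([cfg.prior_a + x_se, cfg.prior_a + x_sp])
    b_post = np.concatenate([cfg.prior_b + data.n1 - x_se,
                             cfg.prior_b + data.n0 - x_sp])
    sigma = np.zeros((2 * m, 2 * m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sigma[:m, :m] = _indicator_correlation(data.correct_cases().astype(float))
        sigma[m:, m:] = _indicator_correlation(data.correct_controls().astype(float))
    sigma = repair_correlation(sigma)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(2 * m))
    z = rng.standard_normal((cfg.posterior_draws, 2 * m)) @ chol.T
    return ndtr(z), a_post, b_post


def mbeta_decide(data: StudyData, hyp: HypothesisSpec,
                 cfg: MBetaConfig | None = None, seed: int = 0) -> McpResult:
    """Bayesian decisions from simultaneous posterior lower bounds.

    Independent Beta(a, b) priors per parameter are updated with the
    binomial counts; joint posterior dependence is approximated by a
    Gaussian copula with the empirical correlation of the correct-decision
    indicators.  A common marginal quantile level ``gamma`` is calibrated
    so that the joint posterior probability that all *binding* parameters
    (one per test under ``lfc_pr = 1``, the endpoint with the smaller
    posterior median margin over its threshold) exceed their lower bounds
    is at least ``1 - alpha``.  Test j is accepted iff both of its bounds
    clear (se0, sp0).  No adjusted p-values are defined.
    """
    cfg = cfg or MBetaConfig()
    rng = np.random.default_rng(seed)
    m = data.m
    u, a_post, b_post = _joint_posterior_uniforms(data, cfg, rng)
    med = beta_dist.ppf(0.5, a_post, b_post)
    margin_se = med[:m] - hyp.se0
    margin_sp = med[m:] - hyp.sp0
    binding_cols = np.where(margin_se <= margin_sp, np.arange(m), np.arange(m) + m)
    min_binding = u[:, binding_cols].min(axis=1)
    min_all = u.min(axis=1)

    def joint_exceed(gamma: float) -> float:
        p_lfc = float(np.mean(min_binding > gamma))
        if cfg.lfc_pr == 1.0:
            return p_lfc
        return cfg.lfc_pr * p_lfc + (1 - cfg.lfc_pr) * float(np.mean(min_all > gamma))

    # largest gamma keeping the joint exceedance probability >= 1 - alpha
    lo, hi = 0.0, hyp.alpha
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if joint_exceed(mid) >= 1 - hyp.alpha:
            lo = mid
        else:
            hi = mid
    gamma = lo
    lower = beta_dist.ppf(gamma, a_post, b_post)
    lb_se, lb_sp = lower[:m], lower[m:]
    decisions = ((lb_se > hyp.se0) & (lb_sp > hyp.sp0)).astype(int)
    return McpResult(
        procedure="mbeta",
        critical_value=float("nan"),
        decisions=decisions,
        adjusted_p=None,
        diagnostics={
            "gamma": gamma,
            "lower_bound_se": lb_se,
            "lower_bound_sp": lb_sp,
            "binding_parameter": np.where(binding_cols < m, "se", "sp"),
            "posterior_a": a_post,
            "posterior_b": b_post,
            "seed": seed,
            "lfc_pr": cfg.lfc_pr,
        },
    )


# ----------------------------------------------------------- adjusted p-values

def adjusted_pvalues(procedure: str, stats: TestStatistics, *,
                     m: int | None = None,
                     r_hat: LfcCorrelation | np.ndarray | None = None,
                     draws: BootstrapDraws | None = None,
                     mvn_seed: int = 0) -> np.ndarray:
    """Multiplicity-adjusted p-values for the per-test minimum statistics."""
    z = stats.z_min
    if procedure == "none":
        return 1 - ndtr(z)
    if procedure == "bonferroni":
        mm = m if m is not None else stats.m
        return np.minimum(1.0, mm * (1 - ndtr(z)))
    if procedure == "maxt":
        if r_hat is None:
            raise ValueError("maxt adjusted p-values need the LFC correlation matrix")
        mat = r_hat.matrix if isinstance(r_hat, LfcCorrelation) else np.asarray(r_hat)
        return np.array([1 - mvn_orthant_prob(zj, mat, seed=mvn_seed) for zj in z])
    if procedure in ("pairs", "wild"):
        if draws is None:
            raise ValueError("bootstrap adjusted p-values need the bootstrap draws")
        ms = draws.max_stats
        return np.array([(1 + np.sum(ms >= zj)) / (draws.B + 1) for zj in z])
    if procedure == "mbeta":
        raise UnsupportedProcedureError("the mBeta procedure does not define adjusted p-values")
    raise UnsupportedProcedureError(f"unknown procedure {procedure!r}")


# ------------------------------------------------------------------- frontend

def fit_procedure(data: StudyData, hyp: HypothesisSpec, procedure: str, *,
                  shrinkage: float = 0.5, B: int = 2000, seed: int = 0,
                  weight_dist: str | Callable = "normal",
                  mbeta_cfg: MBetaConfig | None = None,
                  est: AccuracyEstimate | None = None,
                  stats: TestStatistics | None = None) -> McpResult:
    """Run one multiple comparison procedure end to end on a dataset."""
    if procedure not in PROCEDURES:
        raise UnsupportedProcedureError(
            f"unknown procedure {procedure!r}; choose from {PROCEDURES}")
    if est is None:
        est = estimate_accuracy(data, shrinkage)
    if stats is None:
        stats = wald_statistics(est, hyp)

    if procedure == "mbeta":
        return mbeta_decide(data, hyp, mbeta_cfg, seed)

    diagnostics: dict[str, Any] = {"seed": seed}
    if procedure == "none":
        c = critical_value_none(hyp.alpha)
        adj = adjusted_pvalues("none", stats)
    elif procedure == "bonferroni":
        c = critical_value_bonferroni(hyp.alpha, data.m)
        adj = adjusted_pvalues("bonferroni", stats, m=data.m)
    elif procedure == "maxt":
        r_hat = estimate_lfc_correlation(data, stats)
        c = critical_value_maxt(r_hat, hyp.alpha, rng_seed=seed)
        adj = adjusted_pvalues("maxt", stats, r_hat=r_hat, mvn_seed=seed)
        diagnostics["r_hat"] = r_hat
    elif procedure == "pairs":
        draws, c = pairs_bootstrap(data, est, hyp, B=B, seed=seed)
        adj = adjusted_pvalues("pairs", stats, draws=draws)
        diagnostics.update(draws=draws, B=B)
    else:  # wild
        draws, c = wild_bootstrap(data, est, hyp, B=B, seed=seed, weight_dist=weight_dist)
        adj = adjusted_pvalues("wild", stats, draws=draws)
        diagnostics.update(draws=draws, B=B)

    return McpResult(procedure=procedure, critical_value=c,
                     decisions=decide(stats, c), adjusted_p=adj,
                     diagnostics=diagnostics)
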