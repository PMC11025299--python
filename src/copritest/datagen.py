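"""Synthetic data generators for the two simulation settings.

*LFC setting* — correlated multivariate binary correctness indicators with
each test placed at a least-favourable configuration: one endpoint exactly
at its acceptance boundary, the other degenerate at 1.  Correlated binary
columns are produced by thresholding an equicorrelated latent Gaussian
whose correlation is moment-matched to the requested binary correlation.

*Biomarker setting* — multivariate binormal diagnostic markers (unit
variance, healthy mean 0, diseased mean set from the target AUC via
``mu = sqrt(2) * ndtri(auc)``) dichotomized at cut points, so that each
cut point defines one binary test with known true accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .core import StudyData


class FeasibilityError(ValueError):
    """Requested binary correlation outside the Frechet-feasible range."""


@dataclass(frozen=True)
class TruthTable:
    """Generating accuracy parameters and the implied null classification.

    Test j is a true null iff ``se_true[j] <= se0`` or ``sp_true[j] <= sp0``;
    ``null_mask`` is None when no thresholds were supplied.
    """

    se_true: np.ndarray
    sp_true: np.ndarray
    null_mask: np.ndarray | None = None

    @staticmethod
    def from_truths(se_true, sp_true, se0: float | None = None,
                    sp0: float | None = None) -> "TruthTable":
        se_true = np.asarray(se_true, dtype=float)
        sp_true = np.asarray(sp_true, dtype=float)
        mask = None
        if se0 is not None and sp0 is not None:
            mask = (se_true <= se0) | (sp_true <= sp0)
        return TruthTable(se_true, sp_true, mask)

    @property
    def m(self) -> int:
        return self.se_true.shape[0]


@dataclass(frozen=True)
class LfcConfig:
    """Least-favourable configuration for m tests.

    ``b[j] = 1`` puts sensitivity j at the boundary ``se0`` (specificity
    degenerate at 1); ``b[j] = 0`` the reverse.  Default is the
    alternating vector (1, 0, 1, 0, ...).  Equicorrelations apply among
    the non-degenerate parameters of each endpoint.
    """

    m: int
    se0: float
    sp0: float
    n1: int
    n0: int
    b: tuple[int, ...] = ()
    rho_se: float = 0.0
    rho_sp: float = 0.0

    def __post_init__(self):
        if self.m < 1 or self.n1 < 1 or self.n0 < 1:
            raise ValueError("m, n1, n0 must be positive")
        b = tuple(self.b) or tuple((j + 1) % 2 for j in range(self.m))
        if len(b) != self.m or any(v not in (0, 1) for v in b):
            raise ValueError("b must be a binary vector of length m")
        for r in (self.rho_se, self.rho_sp):
            if not 0.0 <= r < 1.0:
                raise ValueError("equicorrelations must lie in [0, 1)")
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class BiomarkerConfig:
    """Binormal marker model with cut-point-defined tests.

    ``cutpoints`` is a list of (marker index, cut point) pairs, marker
    indices 0-based; several cut points on one marker yield strongly
    correlated tests.
    """

    l: int
    auc: tuple[float, ...]
    n1: int
    n0: int
    cutpoints: tuple[tuple[int, float], ...]
    marker_correlation: float = 0.0

    def __post_init__(self):
        auc = tuple(float(a) for a in np.broadcast_to(self.auc, (self.l,)))
        if any(not 0.5 < a < 1.0 for a in auc):
            raise ValueError("each AUC must lie in (0.5, 1)")
        cps = tuple((int(k), float(c)) for k, c in self.cutpoints)
        if not cps:
            raise ValueError("at least one cut point is required")
        if any(not 0 <= k < self.l for k, _ in cps):
            raise ValueError("cut point refers to an unknown marker")
        if any(not np.isfinite(c) for _, c in cps):
            raise ValueError("cut points must be finite")
        if not -1.0 / max(self.l - 1, 1) < self.marker_correlation < 1.0:
            raise ValueError("marker_correlation yields an invalid correlation matrix")
        object.__setattr__(self, "auc", auc)
        object.__setattr__(self, "cutpoints", cps)

    @property
    def m(self) -> int:
        return len(self.cutpoints)


# ------------------------------------------------------- correlated binaries

def _bvn_density(s: float, t1: float, t2: float) -> float:
    det = 1.0 - s * s
    return np.exp(-(t1 * t1 - 2 * s * t1 * t2 + t2 * t2) / (2 * det)) / (2 * np.pi * np.sqrt(det))


def _upper_orthant(r: float, t1: float, t2: float, p1: float, p2: float) -> float:
    # P(X1 > t1, X2 > t2) = p1*p2 + int_0^r phi2(t1, t2; s) ds  (Plackett)
    if r == 0.0:
        return p1 * p2
    val, _ = quad(_bvn_density, 0.0, r, args=(t1, t2), epsabs=1e-12, limit=200)
    return p1 * p2 + val


def binary_to_normal_correlation(p1: float, p2: float, rho_binary: float) -> float:
    """Latent Gaussian correlation matching a target binary correlation.

    Finds r such that thresholding a standard bivariate normal with
    correlation r at ``ndtri(1 - p_k)`` yields Bernoulli margins
    (p1, p2) with Pearson correlation ``rho_binary``.
    """
    if rho_binary == 0.0:
        return 0.0
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p11 = rho_binary * s + p1 * p2
    lo_f = max(0.0, p1 + p2 - 1.0)
    hi_f = min(p1, p2)
    if not lo_f - 1e-12 <= p11 <= hi_f + 1e-12:
        lo_r = (lo_f - p1 * p2) / s
        hi_r = (hi_f - p1 * p2) / s
        raise FeasibilityError(
            f"binary correlation {rho_binary} infeasible for margins ({p1}, {p2}); "
            f"attainable range is [{lo_r:.6f}, {hi_r:.6f}]")
    t1, t2 = ndtri(1 - p1), ndtri(1 - p2)
    if abs(p11 - hi_f) < 1e-12 and abs(p1 - p2) < 1e-12:
        return 1.0
    if abs(p11 - lo_f) < 1e-12:
        return -1.0

    def f(r):
        return _upper_orthant(r, t1, t2, p1, p2) - p11

    return float(brentq(f, -1 + 1e-10, 1 - 1e-10, xtol=1e-8))


def _equicorr_binary(rng: np.random.Generator, n: int, k: int, p: float,
                     latent_r: float) -> np.ndarray:
    """n x k binary matrix, margins p, latent equicorrelation latent_r."""
    z = rng.standard_normal((n, k))
    if latent_r > 0:
        common = rng.standard_normal((n, 1))
        z = np.sqrt(latent_r) * common + np.sqrt(1 - latent_r) * z
    return (z > ndtri(1 - p)).astype(np.int8)


def generate_lfc_data(cfg: LfcConfig, seed: int | None = None) -> tuple[StudyData, TruthTable]:
    """One synthetic dataset at the least-favourable configuration.

    Correctness matrices Q1 (cases) and Q0 (controls) are generated
    independently; boundary columns are correlated Bernoulli(boundary),
    degenerate columns are constant 1.  Test results follow from
    ``Q = 1(T = D)``: cases show T = Q, controls T = 1 - Q.  Every test is
    a true null.
    """
    rng = np.random.default_rng(seed)
    b = np.asarray(cfg.b)
    idx_se = np.flatnonzero(b == 1)  # sensitivity at boundary
    idx_sp = np.flatnonzero(b == 0)  # specificity at boundary

    q1 = np.ones((cfg.n1, cfg.m), dtype=np.int8)
    q0 = np.ones((cfg.n0, cfg.m), dtype=np.int8)
    if idx_se.size:
        r = binary_to_normal_correlation(cfg.se0, cfg.se0, cfg.rho_se) if idx_se.size > 1 else 0.0
        q1[:, idx_se] = _equicorr_binary(rng, cfg.n1, idx_se.size, cfg.se0, r)
    if idx_sp.size:
        r = binary_to_normal_correlation(cfg.sp0, cfg.sp0, cfg.rho_sp) if idx_sp.size > 1 else 0.0
        q0[:, idx_sp] = _equicorr_binary(rng, cfg.n0, idx_sp.size, cfg.sp0, r)

    t = np.vstack([q1, 1 - q0])
    d = np.concatenate([np.ones(cfg.n1, dtype=np.int8), np.zeros(cfg.n0, dtype=np.int8)])
    data = StudyData(disease_status=d, test_results=t)
    se_true = np.where(b == 1, cfg.se0, 1.0)
    sp_true = np.where(b == 0, cfg.sp0, 1.0)
    truth = TruthTable.from_truths(se_true, sp_true, cfg.se0, cfg.sp0)
    return data, truth


# ---------------------------------------------------------- biomarker setting

def auc_to_mean(auc: float) -> float:
    """Diseased-group mean separation achieving a target binormal AUC."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie in (0, 1)")
    return float(np.sqrt(2.0) * ndtri(auc))


def true_accuracy_biomarker(cfg: BiomarkerConfig, se0: float | None = None,
                            sp0: float | None = None) -> TruthTable:
    """True (se, sp) per cut point: ``se = ndtr(mu - c)``, ``sp = ndtr(c)``."""
    mu = np.array([auc_to_mean(a) for a in cfg.auc])
    k = np.array([k for k, _ in cfg.cutpoints])
    c = np.array([c for _, c in cfg.cutpoints])
    se_true = ndtr(mu[k] - c)
    sp_true = 1.0 - ndtr(-c)
    return TruthTable.from_truths(se_true, sp_true, se0, sp0)


def generate_biomarker_data(cfg: BiomarkerConfig, seed: int | None = None,
                            se0: float | None = None,
                            sp0: float | None = None) -> tuple[StudyData, TruthTable]:
    """One synthetic dataset from the dichotomized binormal marker model."""
    rng = np.random.default_rng(seed)
    mu = np.array([auc_to_mean(a) for a in cfg.auc])
    rho = cfg.marker_correlation
    v1 = rng.standard_normal((cfg.n1, cfg.l))
    v0 = rng.standard_normal((cfg.n0, cfg.l))
    if rho != 0.0 and cfg.l > 1:
        # equicorrelated unit-variance Gaussians via a shared factor
        c1 = rng.standard_normal((cfg.n1, 1))
        c0 = rng.standard_normal((cfg.n0, 1))
        v1 = np.sqrt(rho) * c1 + np.sqrt(1 - rho) * v1
        v0 = np.sqrt(rho) * c0 + np.sqrt(1 - rho) * v0
    v1 = v1 + mu
    k = np.array([k for k, _ in cfg.cutpoints])
    c = np.array([c for _, c in cfg.cutpoints])
    t = np.vstack([(v1[:, k] > c), (v0[:, k] > c)]).astype(np.int8)
    d = np.concatenate([np.ones(cfg.n1, dtype=np.int8), np.zeros(cfg.n0, dtype=np.int8)])
    data = StudyData(disease_status=d, test_results=t)
    return data, true_accuracy_biomarker(cfg, se0, sp0)


def pooled_quantile_cutpoints(auc: float, prevalence: float,
                              probs) -> np.ndarray:
    """Cut points at given quantiles of the pooled marker distribution.

    The pooled marker is the two-component normal mixture
    ``(1 - prev) N(0,1) + prev N(mu, 1)`` with mu from the AUC.
    """
    mu = auc_to_mean(auc)

    def cdf(x):
        return (1 - prevalence) * ndtr(x) + prevalence * ndtr(x - mu)

    out = []
    for p in np.atleast_1d(probs):
        out.append(brentq(lambda x: cdf(x) - p, -10, mu + 10, xtol=1e-10))
    return np.array(out)
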