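"""Data model, accuracy estimation and the co-primary decision rule.

A study compares ``m`` binary index tests against a binary reference
standard on ``n`` subjects.  Each test ``j`` is judged by its sensitivity
``se_j = P(T_j = 1 | D = 1)`` and specificity ``sp_j = P(T_j = 0 | D = 0)``
against minimal acceptance criteria ``(se0, sp0)``.  A test is declared
acceptable only if *both* endpoints clear their threshold
(intersection-union principle), which is expressed through the minimum of
the two Wald statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidDataError(ValueError):
    """Raised when a study dataset violates the data-model invariants."""


class DegenerateVarianceError(ValueError):
    """Raised when an accuracy estimate of 0 or 1 makes the Wald variance zero."""


def _as_binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.floating) and np.isnan(a).any():
        raise InvalidDataError(f"{name} contains missing values; complete data required")
    a = a.astype(np.int8, copy=False)
    if not np.isin(a, (0, 1)).all():
        raise InvalidDataError(f"{name} must contain only 0/1 entries")
    return a


@dataclass(frozen=True)
class StudyData:
    """Subject-level results of a within-subject diagnostic accuracy study.

    Parameters
    ----------
    disease_status : array of shape (n,)
        Reference-standard status per subject, 1 = diseased.
    test_results : array of shape (n, m)
        Binary index-test results, one column per candidate test.
    test_labels : sequence of str, optional
        Identifiers for the m tests; defaults to ``T1..Tm``.
    """

    disease_status: np.ndarray
    test_results: np.ndarray
    test_labels: tuple[str, ...] = ()

    def __post_init__(self):
        d = _as_binary(self.disease_status, "disease_status").ravel()
        t = _as_binary(self.test_results, "test_results")
        if t.ndim == 1:
            t = t[:, None]
        if t.ndim != 2:
            raise InvalidDataError("test_results must be a 2-d array")
        if t.shape[0] != d.shape[0]:
            raise InvalidDataError(
                f"disease_status has {d.shape[0]} subjects but test_results has {t.shape[0]} rows"
            )
        if t.shape[1] < 1:
            raise InvalidDataError("at least one index test is required")
        if d.sum() < 1 or (1 - d).sum() < 1:
            raise InvalidDataError("both the diseased and the non-diseased group must be non-empty")
        labels = tuple(self.test_labels) or tuple(f"T{j + 1}" for j in range(t.shape[1]))
        if len(labels) != t.shape[1]:
            raise InvalidDataError("test_labels length must match the number of test columns")
        object.__setattr__(self, "disease_status", d)
        object.__setattr__(self, "test_results", t)
        object.__setattr__(self, "test_labels", labels)

    @property
    def n(self) -> int:
        return self.disease_status.shape[0]

    @property
    def n1(self) -> int:
        return int(self.disease_status.sum())

    @property
    def n0(self) -> int:
        return self.n - self.n1

    @property
    def m(self) -> int:
        return self.test_results.shape[1]

    def cases(self) -> np.ndarray:
        """Test-result rows of diseased subjects, shape (n1, m)."""
        return self.test_results[self.disease_status == 1]

    def controls(self) -> np.ndarray:
        """Test-result rows of non-diseased subjects, shape (n0, m)."""
        return self.test_results[self.disease_status == 0]

    def correct_cases(self) -> np.ndarray:
        """Correct-decision indicators among cases (= the case rows themselves)."""
        return self.cases()

    def correct_controls(self) -> np.ndarray:
        """Correct-decision indicators among controls (1 - test result)."""
        return 1 - self.controls()


@dataclass(frozen=True)
class HypothesisSpec:
    """Minimal acceptance criteria and one-sided significance level."""

    se0: float
    sp0: float
    alpha: float = 0.025

    def __post_init__(self):
        if not 0.0 < self.se0 < 1.0:
            raise ValueError(f"se0 must lie in (0, 1), got {self.se0}")
        if not 0.0 < self.sp0 < 1.0:
            raise ValueError(f"sp0 must lie in (0, 1), got {self.sp0}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must lie in (0, 0.5), got {self.alpha}")


@dataclass(frozen=True)
class AccuracyEstimate:
    """Per-test sensitivity/specificity estimates with optional shrinkage.

    ``se_hat[j] = (n11[j] + h) / (n1 + 2h)`` and analogously for
    specificity with the control-group counts; ``h = 0`` gives the plain
    maximum-likelihood proportions.
    """

    se_hat: np.ndarray
    sp_hat: np.ndarray
    n11: np.ndarray
    n00: np.ndarray
    n1: int
    n0: int
    shrinkage: float = 0.0

    @property
    def shrinkage_applied(self) -> bool:
        return self.shrinkage > 0

    @property
    def m(self) -> int:
        return self.se_hat.shape[0]


@dataclass(frozen=True)
class TestStatistics:
    """Wald statistics per test and endpoint, plus their minimum."""

    __test__ = False  # not a pytest class

    z_se: np.ndarray
    z_sp: np.ndarray
    z_min: np.ndarray
    binding_endpoint: np.ndarray = field(default=None)  # array of "se"/"sp"

    @property
    def m(self) -> int:
        return self.z_min.shape[0]


def estimate_accuracy(data: StudyData, shrinkage_pseudocount: float = 0.5) -> AccuracyEstimate:
    """Estimate sensitivity and specificity for every index test.

    With pseudo-count ``h`` the estimates are shrunk towards 0.5 by adding
    ``h`` pseudo-successes and ``h`` pseudo-failures per subgroup, which
    keeps all estimates strictly inside (0, 1) and the Wald variances
    positive.  ``h = 0`` reproduces the raw proportions.
    """
    h = float(shrinkage_pseudocount)
    if h < 0:
        raise ValueError("shrinkage_pseudocount must be non-negative")
    n11 = data.cases().sum(axis=0)
    n00 = (1 - data.controls()).sum(axis=0)
    se_hat = (n11 + h) / (data.n1 + 2 * h)
    sp_hat = (n00 + h) / (data.n0 + 2 * h)
    return AccuracyEstimate(
        se_hat=se_hat.astype(float),
        sp_hat=sp_hat.astype(float),
        n11=n11,
        n00=n00,
        n1=data.n1,
        n0=data.n0,
        shrinkage=h,
    )


def wald_statistics(est: AccuracyEstimate, hyp: HypothesisSpec,
                    n0: int | None = None, n1: int | None = None) -> TestStatistics:
    """Wald statistics ``Z_j^se, Z_j^sp`` and their per-test minimum.

    ``Z_j^se = (se_hat_j - se0) / sqrt(se_hat_j (1 - se_hat_j) / n1)`` and
    analogously for specificity.  The binding endpoint records which of the
    two attains the minimum (ties resolved as ``se`` for reproducibility).
    """
    n1 = est.n1 if n1 is None else n1
    n0 = est.n0 if n0 is None else n0
    for name, v in (("se", est.se_hat), ("sp", est.sp_hat)):
        if np.any((v <= 0) | (v >= 1)):
            raise DegenerateVarianceError(
                f"{name} estimate of exactly 0 or 1 gives zero Wald variance; "
                "use a positive shrinkage pseudo-count"
            )
    z_se = (est.se_hat - hyp.se0) / np.sqrt(est.se_hat * (1 - est.se_hat) / n1)
    z_sp = (est.sp_hat - hyp.sp0) / np.sqrt(est.sp_hat * (1 - est.sp_hat) / n0)
    z_min = np.minimum(z_se, z_sp)
    binding = np.where(z_se <= z_sp, "se", "sp")
    return TestStatistics(z_se=z_se, z_sp=z_sp, z_min=z_min, binding_endpoint=binding)


def decide(stats: TestStatistics, c_alpha: float) -> np.ndarray:
    """Intersection-union decisions: reject test j iff ``min(Z_se, Z_sp) > c``."""
    if np.isnan(c_alpha):
        raise ValueError("critical value must not be NaN")
    return (stats.z_min > c_alpha).astype(int)
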