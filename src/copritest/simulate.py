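"""Simulation engine estimating FWER and disjunctive power.

Every replicate draws one synthetic dataset and applies *all* requested
procedures to that same dataset, so procedures are compared on identical
data.  Replicate r uses seed ``base_seed + r`` for data generation and an
independent stream ``base_seed + 1_000_000 + r`` for procedure-internal
randomness (bootstrap draws, quantile integration).

FWER is the fraction of replicates with at least one rejection of a true
null hypothesis; disjunctive power the fraction with at least one
rejection of a false null (undefined, and reported as None, when the
scenario contains no false nulls, as in the LFC setting).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._mvn import mvn_orthant_prob
from .core import HypothesisSpec, estimate_accuracy, wald_statistics
from .datagen import BiomarkerConfig, LfcConfig, TruthTable, generate_biomarker_data, generate_lfc_data
from .mcp import (
    MBetaConfig,
    critical_value_bonferroni,
    critical_value_none,
    estimate_lfc_correlation,
    mbeta_decide,
    pairs_bootstrap,
    wild_bootstrap,
)

logger = logging.getLogger(__name__)

_PROC_SEED_OFFSET = 1_000_000


@dataclass(frozen=True)
class SimScenario:
    generator: LfcConfig | BiomarkerConfig
    hypothesis: HypothesisSpec
    procedures: tuple[str, ...]
    nsim: int
    base_seed: int = 0
    shrinkage: float = 0.5
    bootstrap_B: int = 1000
    mbeta_config: MBetaConfig | None = None
    mvn_points: int = 4096

    def __post_init__(self):
        if self.nsim < 1:
            raise ValueError("nsim must be >= 1")
        object.__setattr__(self, "procedures", tuple(self.procedures))


@dataclass
class ProcedureSummary:
    fwer: float
    fwer_se: float
    power: float | None
    power_se: float | None
    false_rejection_reps: int
    true_rejection_reps: int
    failed_reps: int


@dataclass
class SimResult:
    scenario: SimScenario
    per_procedure: dict[str, ProcedureSummary]
    nsim: int
    elapsed_seconds: float
    extra: dict[str, Any] = field(default_factory=dict)


def mc_se(p: float, nsim: int) -> float:
    """Monte-Carlo standard error sqrt(p (1 - p) / nsim) of a proportion."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    return float(np.sqrt(p * (1 - p) / nsim))


def classify_rejections(decisions: np.ndarray, truth: TruthTable) -> tuple[int, int]:
    """(any false rejection, any true rejection) flags for one replicate."""
    dec = np.asarray(decisions).astype(bool)
    if truth.null_mask is None:
        raise ValueError("truth table carries no null classification")
    if dec.shape[0] != truth.m:
        raise ValueError("decision vector and truth table sizes differ")
    false_rej = bool(np.any(dec & truth.null_mask))
    true_rej = bool(np.any(dec & ~truth.null_mask))
    return int(false_rej), int(true_rej)


def _generate(generator, seed, hyp):
    if isinstance(generator, LfcConfig):
        return generate_lfc_data(generator, seed)
    return generate_biomarker_data(generator, seed, hyp.se0, hyp.sp0)


def _maxt_decisions(data, stats, alpha, c_none, c_bonf, seed, n_points) -> np.ndarray:
    """maxT decisions via orthant-probability evaluation at candidate statistics.

    z > c_maxt  iff  P(max of N(0, R_hat) <= z) > 1 - alpha, and
    c_none <= c_maxt <= c_bonf, so only statistics in (c_none, c_bonf]
    need an MVN evaluation.  This avoids the quantile bisection per
    replicate while giving identical decisions.
    """
    z = stats.z_min
    dec = (z > c_bonf).astype(int)
    cand = np.flatnonzero((z > c_none) & (z <= c_bonf))
    if cand.size:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant LFC columns are expected here
            r_hat = estimate_lfc_correlation(data, stats)
        for j in cand:
            if mvn_orthant_prob(z[j], r_hat.matrix, n_points=n_points, seed=seed) > 1 - alpha:
                dec[j] = 1
    return dec


def run_scenario(scn: SimScenario) -> SimResult:
    """Estimate FWER and disjunctive power for every procedure in the scenario."""
    hyp = scn.hypothesis
    alpha = hyp.alpha
    c_none = critical_value_none(alpha)
    procs = scn.procedures
    c_bonf = critical_value_bonferroni(alpha, scn.generator.m)

    false_cnt = {p: 0 for p in procs}
    true_cnt = {p: 0 for p in procs}
    fail_cnt = {p: 0 for p in procs}
    has_false_null = None

    t_start = time.time()
    for r in range(1, scn.nsim + 1):
        data, truth = _generate(scn.generator, scn.base_seed + r, hyp)
        if truth.null_mask is None:
            raise ValueError("generator truth table lacks null classification")
        if has_false_null is None:
            has_false_null = bool(np.any(~truth.null_mask))
        est = estimate_accuracy(data, scn.shrinkage)
        stats = wald_statistics(est, hyp)
        proc_seed = scn.base_seed + _PROC_SEED_OFFSET + r
        for p in procs:
            try:
                if p == "none":
                    dec = (stats.z_min > c_none).astype(int)
                elif p == "bonferroni":
                    dec = (stats.z_min > c_bonf).astype(int)
                elif p == "maxt":
                    dec = _maxt_decisions(data, stats, alpha, c_none, c_bonf,
                                          proc_seed, scn.mvn_points)
                elif p == "pairs":
                    _, c = pairs_bootstrap(data, est, hyp, B=scn.bootstrap_B, seed=proc_seed)
                    dec = (stats.z_min > c).astype(int)
                elif p == "wild":
                    _, c = wild_bootstrap(data, est, hyp, B=scn.bootstrap_B, seed=proc_seed)
                    dec = (stats.z_min > c).astype(int)
                elif p == "mbeta":
                    dec = mbeta_decide(data, hyp, scn.mbeta_config, proc_seed).decisions
                else:
                    raise ValueError(f"unknown procedure {p!r}")
            except Exception:
                fail_cnt[p] += 1
                logger.exception("procedure %s failed on replicate %d", p, r)
                continue
            f, t = classify_rejections(dec, truth)
            false_cnt[p] += f
            true_cnt[p] += t
        if r % 1000 == 0:
            logger.info("replicate %d/%d (%.1f s)", r, scn.nsim, time.time() - t_start)

    summaries = {}
    for p in procs:
        n_ok = scn.nsim - fail_cnt[p]
        fwer = false_cnt[p] / n_ok if n_ok else float("nan")
        if has_false_null:
            power = true_cnt[p] / n_ok if n_ok else float("nan")
            power_se = mc_se(power, n_ok) if n_ok else None
        else:
            power = power_se = None
        summaries[p] = ProcedureSummary(
            fwer=fwer,
            fwer_se=mc_se(fwer, n_ok) if n_ok else float("nan"),
            power=power,
            power_se=power_se,
            false_rejection_reps=false_cnt[p],
            true_rejection_reps=true_cnt[p],
            failed_reps=fail_cnt[p],
        )
    return SimResult(scenario=scn, per_procedure=summaries, nsim=scn.nsim,
                     elapsed_seconds=time.time() - t_start)
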