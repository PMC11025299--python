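import numpy as np
import pytest
from scipy.special import ndtr, ndtri
from scipy.stats import beta as beta_dist

from copritest import (
    HypothesisSpec,
    MBetaConfig,
    StudyData,
    adjusted_pvalues,
    critical_value_bonferroni,
    critical_value_maxt,
    critical_value_none,
    estimate_accuracy,
    estimate_lfc_correlation,
    fit_procedure,
    mbeta_decide,
    pairs_bootstrap,
    wald_statistics,
    wild_bootstrap,
)
from copritest.core import InvalidDataError
from copritest.mcp import (
    LfcCorrelation,
    UnsupportedProcedureError,
    bootstrap_critical_value,
)
from conftest import make_random_study


class TestNormalCriticalValues:
    def test_none_median(self):
        assert critical_value_none(0.4999) == pytest.approx(0.0, abs=1e-3)

    def test_none_quantiles(self):
        assert critical_value_none(0.025) == pytest.approx(1.95996, abs=1e-4)
        assert critical_value_none(0.05) == pytest.approx(1.64485, abs=1e-4)

    def test_bonferroni_reduces_at_m1(self):
        assert critical_value_bonferroni(0.025, 1) == critical_value_none(0.025)

    def test_bonferroni_value(self):
        assert critical_value_bonferroni(0.025, 10) == pytest.approx(ndtri(0.9975), abs=1e-9)
        assert critical_value_bonferroni(0.025, 10) == pytest.approx(2.8070, abs=1e-3)

    def test_bonferroni_monotone_in_m(self):
        assert critical_value_bonferroni(0.025, 10) > critical_value_bonferroni(0.025, 5)


class TestLfcCorrelation:
    def test_identical_se_binding_columns(self, hyp):
        cases = np.array([[1, 1], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]])
        controls = np.zeros((6, 2), dtype=int)
        data = StudyData(np.array([1] * 6 + [0] * 6), np.vstack([cases, controls]))
        stats = wald_statistics(estimate_accuracy(data), hyp)
        assert (stats.binding_endpoint == "se").all()
        r = estimate_lfc_correlation(data, stats)
        assert r.matrix[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_cross_endpoint_zero(self):
        # test 1 binds on se (poor sensitivity), test 2 on sp (poor specificity)
        rng = np.random.default_rng(3)
        cases = np.column_stack([rng.binomial(1, 0.75, 50), rng.binomial(1, 0.99, 50)])
        controls = np.column_stack([rng.binomial(1, 0.01, 50), rng.binomial(1, 0.35, 50)])
        data = StudyData(np.array([1] * 50 + [0] * 50), np.vstack([cases, controls]))
        stats = wald_statistics(estimate_accuracy(data), HypothesisSpec(0.8, 0.7, 0.025))
        assert stats.binding_endpoint.tolist() == ["se", "sp"]
        r = estimate_lfc_correlation(data, stats)
        assert r.matrix[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_pearson(self, six_case_study, hyp):
        # case columns (1,1,0,1,0,1) and (1,0,0,1,1,1): means 2/3,
        # E[XY] = 3/6, cov = 1/2 - 4/9 = 1/18, var = 2/9 each -> r = 1/4
        stats = wald_statistics(estimate_accuracy(six_case_study), hyp)
        assert (stats.binding_endpoint == "se").all()
        r = estimate_lfc_correlation(six_case_study, stats)
        assert r.matrix[0, 1] == pytest.approx(0.25, abs=1e-9)

    def test_constant_column_warns_and_zeroes(self, hyp):
        cases = np.column_stack([np.ones(8, dtype=int), np.tile([1, 0], 4)])
        controls = np.zeros((8, 2), dtype=int)
        data = StudyData(np.array([1] * 8 + [0] * 8), np.vstack([cases, controls]))
        est = estimate_accuracy(data)
        stats = wald_statistics(est, HypothesisSpec(0.95, 0.7, 0.025))
        assert (stats.binding_endpoint == "se").all()
        with pytest.warns(UserWarning, match="constant"):
            r = estimate_lfc_correlation(data, stats)
        assert r.matrix[0, 1] == 0.0


class TestMaxT:
    def test_m1_reduction(self):
        r = LfcCorrelation(np.eye(1), np.array(["se"]))
        assert critical_value_maxt(r, 0.025) == pytest.approx(critical_value_none(0.025))

    def test_independence_closed_form(self):
        c = critical_value_maxt(np.eye(2), 0.025)
        assert c == pytest.approx(ndtri(np.sqrt(0.975)), abs=3e-3)

    def test_all_ones_equals_unadjusted(self):
        c = critical_value_maxt(np.ones((4, 4)), 0.025)
        assert c == pytest.approx(critical_value_none(0.025), abs=3e-3)

    def test_monte_carlo_oracle(self):
        # brute-force equicoordinate quantile from MVN draws
        rho = 0.5
        corr = np.full((3, 3), rho)
        np.fill_diagonal(corr, 1.0)
        rng = np.random.default_rng(42)
        draws = rng.multivariate_normal(np.zeros(3), corr, size=400_000)
        oracle = np.quantile(draws.max(axis=1), 0.975)
        assert critical_value_maxt(corr, 0.025) == pytest.approx(oracle, abs=0.01)

    def test_ordering_and_nesting(self, hyp):
        for seed in range(6):
            data = make_random_study(seed, n1=35, n0=45, m=4)
            res = {p: fit_procedure(data, hyp, p, seed=seed)
                   for p in ("none", "bonferroni", "maxt")}
            c_none = res["none"].critical_value
            c_maxt = res["maxt"].critical_value
            c_bonf = res["bonferroni"].critical_value
            assert c_none <= c_maxt + 1e-9 <= c_bonf + 1e-6
            assert np.all(res["bonferroni"].decisions <= res["maxt"].decisions)
            assert np.all(res["maxt"].decisions <= res["none"].decisions)


class TestBootstrapQuantileRule:
    def test_constant_sample(self):
        assert bootstrap_critical_value(np.full(200, 1.7), 0.025) == pytest.approx(1.7)

    def test_rank_by_hand(self):
        # B = 4, alpha = 0.25: rank ceil(0.75 * 4) = 3 -> third order statistic
        assert bootstrap_critical_value(np.array([2.0, -1.0, 1.0, 0.0]), 0.25) == 1.0


class TestPairsBootstrap:
    def test_deterministic(self, hyp):
        data = make_random_study(1, m=3)
        est = estimate_accuracy(data)
        d1, c1 = pairs_bootstrap(data, est, hyp, B=300, seed=9)
        d2, c2 = pairs_bootstrap(data, est, hyp, B=300, seed=9)
        assert np.array_equal(d1.max_stats, d2.max_stats)
        assert c1 == c2

    def test_seed_changes_draws(self, hyp):
        data = make_random_study(1, m=3)
        est = estimate_accuracy(data)
        d1, _ = pairs_bootstrap(data, est, hyp, B=300, seed=1)
        d2, _ = pairs_bootstrap(data, est, hyp, B=300, seed=2)
        assert not np.array_equal(d1.max_stats, d2.max_stats)

    def test_b_too_small(self, hyp):
        data = make_random_study(1)
        with pytest.raises(ValueError, match="B >= 100"):
            pairs_bootstrap(data, estimate_accuracy(data), hyp, B=50)

    def test_tiny_group_rejected(self, hyp):
        data = StudyData(np.array([1, 0, 0, 0]), np.array([[1], [0], [0], [1]]))
        with pytest.raises(InvalidDataError):
            pairs_bootstrap(data, estimate_accuracy(data), hyp, B=200)

    def test_m1_near_normal_quantile(self):
        # large-sample oracle: centered binding statistic is ~N(0,1)
        data = make_random_study(11, n1=1000, n0=1000, m=1, se=0.9, sp=0.75)
        hyp = HypothesisSpec(0.8, 0.7, 0.025)
        _, c = pairs_bootstrap(data, estimate_accuracy(data), hyp, B=2000, seed=0)
        assert c == pytest.approx(ndtri(0.975), abs=0.15)


class TestWildBootstrap:
    def test_zero_weights_null_perturbation(self, hyp):
        data = make_random_study(2, m=3)
        est = estimate_accuracy(data)
        draws, c = wild_bootstrap(data, est, hyp, B=200, seed=0, weight_dist="zero")
        assert np.all(draws.max_stats == 0.0)
        assert c == 0.0

    def test_zero_residuals(self):
        # perfect tests with h = 0: all residuals vanish
        d = np.array([1] * 5 + [0] * 5)
        t = np.array([[1]] * 5 + [[0]] * 5)
        data = StudyData(d, t)
        est = estimate_accuracy(data, 0.0)
        draws, c = wild_bootstrap(data, est, HypothesisSpec(0.8, 0.7, 0.025), B=150, seed=1)
        assert np.all(draws.max_stats == 0.0)
        assert c == 0.0

    def test_deterministic(self, hyp):
        data = make_random_study(3, m=2)
        est = estimate_accuracy(data)
        d1, c1 = wild_bootstrap(data, est, hyp, B=250, seed=4)
        d2, c2 = wild_bootstrap(data, est, hyp, B=250, seed=4)
        assert np.array_equal(d1.max_stats, d2.max_stats) and c1 == c2

    def test_m1_near_normal_quantile(self):
        data = make_random_study(12, n1=1000, n0=1000, m=1, se=0.9, sp=0.75)
        hyp = HypothesisSpec(0.8, 0.7, 0.025)
        _, c = wild_bootstrap(data, estimate_accuracy(data), hyp, B=2000, seed=0)
        assert c == pytest.approx(ndtri(0.975), abs=0.15)

    def test_unknown_weight_dist(self, hyp):
        data = make_random_study(1)
        with pytest.raises(ValueError, match="weight"):
            wild_bootstrap(data, estimate_accuracy(data), hyp, B=200, weight_dist="cauchy")


class TestMBeta:
    def single_test_data(self, x, n1, y, n0):
        cases = np.array([1] * x + [0] * (n1 - x))
        controls = np.array([0] * y + [1] * (n0 - y))
        return StudyData(np.array([1] * n1 + [0] * n0),
                         np.concatenate([cases, controls])[:, None])

    def test_conjugate_update(self, hyp):
        data = self.single_test_data(27, 30, 25, 30)
        res = mbeta_decide(data, hyp, MBetaConfig(), seed=0)
        a = res.diagnostics["posterior_a"][0]
        b = res.diagnostics["posterior_b"][0]
        assert (a, b) == (28, 4)
        assert a / (a + b) == pytest.approx(0.875)

    def test_saturated_count(self, hyp):
        data = self.single_test_data(30, 30, 25, 30)
        res = mbeta_decide(data, hyp, MBetaConfig(), seed=0)
        a = res.diagnostics["posterior_a"][0]
        b = res.diagnostics["posterior_b"][0]
        assert a / (a + b) == pytest.approx(31 / 32)  # posterior mean (n+1)/(n+2)

    def test_m1_bound_matches_beta_quantile(self, hyp):
        data = self.single_test_data(27, 30, 28, 30)
        res = mbeta_decide(data, hyp, MBetaConfig(posterior_draws=40_000), seed=5)
        lb = res.diagnostics["lower_bound_se"][0]
        binding = res.diagnostics["binding_parameter"][0]
        assert binding == "se"
        exact = beta_dist.ppf(hyp.alpha, 28, 4)
        assert lb == pytest.approx(exact, abs=0.01)

    def test_lfc_pr_validation(self):
        with pytest.raises(ValueError, match="lfc_pr"):
            MBetaConfig(lfc_pr=2.0)

    def test_small_draws_warns(self):
        with pytest.warns(UserWarning, match="posterior_draws"):
            MBetaConfig(posterior_draws=100)

    def test_no_adjusted_p(self, hyp):
        data = self.single_test_data(27, 30, 28, 30)
        res = mbeta_decide(data, hyp, MBetaConfig(), seed=0)
        assert res.adjusted_p is None


class TestAdjustedPValues:
    def stats_for(self, data, hyp):
        return wald_statistics(estimate_accuracy(data), hyp)

    def test_none_symmetry(self, hyp):
        data = make_random_study(0, m=2)
        stats = self.stats_for(data, hyp)
        p = adjusted_pvalues("none", stats)
        assert np.allclose(p, 1 - ndtr(stats.z_min))

    def test_bonferroni_inverts_critical_value(self):
        from copritest.core import TestStatistics
        z = np.array([critical_value_bonferroni(0.025, 10)])
        stats = TestStatistics(z_se=z, z_sp=z + 1, z_min=z, binding_endpoint=np.array(["se"]))
        p = adjusted_pvalues("bonferroni", stats, m=10)
        assert p[0] == pytest.approx(0.025, abs=1e-6)

    def test_monotone_in_z(self, hyp):
        from copritest.core import TestStatistics
        z = np.array([0.0, 1.0, 2.0, 3.0, 8.0])
        stats = TestStatistics(z_se=z, z_sp=z, z_min=z, binding_endpoint=np.full(5, "se"))
        for proc in ("none", "bonferroni"):
            p = adjusted_pvalues(proc, stats, m=3)
            assert np.all(np.diff(p) <= 0)
        assert adjusted_pvalues("none", stats)[0] == pytest.approx(0.5)

    def test_mbeta_unsupported(self, hyp):
        stats = self.stats_for(make_random_study(0), hyp)
        with pytest.raises(UnsupportedProcedureError):
            adjusted_pvalues("mbeta", stats)

    @pytest.mark.parametrize("proc", ["none", "bonferroni", "maxt", "pairs", "wild"])
    def test_duality_with_decisions(self, proc, hyp):
        for seed in (0, 1, 2):
            data = make_random_study(seed, n1=50, n0=70, m=3, se=0.9, sp=0.8)
            res = fit_procedure(data, hyp, proc, seed=seed, B=500)
            dual = (res.adjusted_p <= hyp.alpha).astype(int)
            assert np.array_equal(res.decisions, dual), (proc, seed)


class TestFitProcedure:
    def test_unknown_procedure(self, hyp):
        with pytest.raises(UnsupportedProcedureError):
            fit_procedure(make_random_study(0), hyp, "holm")

    def test_result_fields(self, hyp):
        data = make_random_study(4, m=3)
        res = fit_procedure(data, hyp, "maxt", seed=1)
        assert res.procedure == "maxt"
        assert res.decisions.shape == (3,)
        assert "r_hat" in res.diagnostics
        assert np.all((res.adjusted_p >= 0) & (res.adjusted_p <= 1))
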