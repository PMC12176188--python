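"""Hypothesis tests, confidence intervals, and pseudo-R²."""

import numpy as np
import pytest
from scipy import stats

from fastkendall import (
    ExactTestError,
    InsufficientDataError,
    NullTable,
    PairedSample,
    TestSpec,
    confidence_interval,
    kendall_test,
    pseudo_r2,
)


class TestArcadeWorkedExample:
    """The n=10 doctorates-vs-arcade-revenue test, all printed numbers."""

    def test_exact_greater(self, arcade):
        res = kendall_test(arcade, TestSpec(alternative="greater", conf_level=0.80))
        assert res.method.endswith("(exact test)")
        assert res.statistic == 41
        assert res.tau == pytest.approx(0.8222222, abs=1e-7)
        assert res.p_value == pytest.approx(0.0001788, abs=5e-8)

    def test_exact_two_sided(self, arcade):
        res = kendall_test(arcade, TestSpec(alternative="two-sided"))
        assert res.statistic == 41
        assert res.p_value == pytest.approx(0.0003577, abs=5e-8)

    def test_exact_less_accepts(self, arcade):
        res = kendall_test(arcade, TestSpec(alternative="less"))
        assert res.p_value > 0.999

    def test_normal_approx_with_continuity(self, arcade):
        res = kendall_test(
            arcade,
            TestSpec(alternative="two-sided", exact_mode="approx", continuity=True),
        )
        assert res.statistic_name == "z"
        assert res.p_value == pytest.approx(0.0012822, abs=5e-7)

    def test_80pct_one_sided_ci(self, arcade):
        res = kendall_test(arcade, TestSpec(alternative="greater", conf_level=0.80))
        assert res.ci_low == pytest.approx(0.5038182, abs=1e-3)
        assert res.ci_high == 1.0

    def test_render_contains_key_numbers(self, arcade):
        text = kendall_test(
            arcade, TestSpec(alternative="greater", conf_level=0.80)
        ).render("arcade")
        assert "tau = 0.82222" in text
        assert "p-value = 0.0001788" in text
        assert "true tau is greater than 0" in text
        assert "80 percent confidence interval" in text
        assert "0.5038182" in text


class TestExactPath:
    def test_force_exact_with_ties_raises(self):
        tied = PairedSample([1, 1, 2, 3], [4, 3, 2, 1])
        with pytest.raises(ExactTestError):
            kendall_test(tied, TestSpec(exact_mode="exact"))

    def test_auto_switches_to_approx_for_ties(self):
        tied = PairedSample([1, 1, 2, 3, 5], [4, 3, 2, 1, 0])
        res = kendall_test(tied)
        assert res.statistic_name == "z"
        assert "approximation" in res.method

    def test_tails_overlap_at_observed_point(self, rng):
        """p_greater + p_less >= 1: both tails include the observation."""
        table = NullTable(15)
        for _ in range(25):
            n = int(rng.integers(3, 16))
            sample = PairedSample(rng.permutation(n).astype(float),
                                  rng.permutation(n).astype(float))
            pg = kendall_test(sample, TestSpec(alternative="greater"),
                              null_table=table).p_value
            pl = kendall_test(sample, TestSpec(alternative="less"),
                              null_table=table).p_value
            assert pg + pl >= 1.0 - 1e-12

    def test_exact_matches_scipy_exact(self, rng):
        """Cross-check two-sided exact p against scipy's exact method."""
        for n in (6, 9, 12):
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            ours = kendall_test(PairedSample(x, y), TestSpec()).p_value
            ref = stats.kendalltau(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_vs_approx_agree_moderate_n(self, rng):
        """No-tie samples, n in 30..49: exact and continuity-corrected
        normal two-sided p-values differ by < 0.01 (the correction
        matches the exact tail's inclusion of the observed point)."""
        table = NullTable(49)
        for _ in range(30):
            n = int(rng.integers(30, 50))
            sample = PairedSample(rng.standard_normal(n), rng.standard_normal(n))
            p_exact = kendall_test(
                sample, TestSpec(exact_mode="exact"), null_table=table
            ).p_value
            p_approx = kendall_test(
                sample, TestSpec(exact_mode="approx", continuity=True)
            ).p_value
            assert abs(p_exact - p_approx) < 0.01


class TestApproxPath:
    def test_no_tie_variance_reduction(self, rng):
        """Without ties z uses v = n(n-1)(2n+5)/18 exactly."""
        n = 40
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = kendall_test(PairedSample(x, y), TestSpec(exact_mode="approx"))
        c = stats.kendalltau(x, y).statistic * (n * (n - 1) / 2)
        v = n * (n - 1) * (2 * n + 5) / 18.0
        assert res.statistic == pytest.approx(c / np.sqrt(v), abs=1e-9)

    def test_tied_data_matches_scipy_asymptotic(self, rng):
        """Tie-corrected z-test p equals scipy's asymptotic tau-b test."""
        for _ in range(10):
            n = 60
            x = rng.integers(0, 8, n).astype(float)
            y = (x + rng.integers(0, 6, n)).astype(float)
            res = kendall_test(PairedSample(x, y), TestSpec(exact_mode="approx"))
            ref = stats.kendalltau(x, y, method="asymptotic").pvalue
            assert res.p_value == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_continuity_shrinks_statistic(self, arcade):
        plain = kendall_test(arcade, TestSpec(exact_mode="approx"))
        corrected = kendall_test(
            arcade, TestSpec(exact_mode="approx", continuity=True)
        )
        assert abs(corrected.statistic) < abs(plain.statistic)
        assert corrected.p_value > plain.p_value


class TestConfidenceInterval:
    def test_symmetric_about_zero(self):
        low, high = confidence_interval(0.0, 25, TestSpec())
        assert low == pytest.approx(-high, abs=1e-15)

    def test_clamped_to_valid_range(self):
        low, high = confidence_interval(0.95, 5, TestSpec(conf_level=0.99))
        assert low >= -1.0 and high == 1.0

    def test_widens_to_full_range_as_conf_approaches_one(self):
        low, high = confidence_interval(0.2, 10, TestSpec(conf_level=1 - 1e-12))
        assert (low, high) == (-1.0, 1.0)

    def test_requires_n_at_least_3(self):
        with pytest.raises(InsufficientDataError):
            confidence_interval(0.5, 2, TestSpec())

    def test_coverage_on_bivariate_normal(self):
        """95% CI covers the true tau in >= 90% of replicates (n=200)."""
        from fastkendall import SyntheticSpec, generate_sample, knight_tau
        from fastkendall.simulate import tau_from_rho

        rho = 0.5
        true_tau = tau_from_rho(rho)
        spec = TestSpec(conf_level=0.95)
        covered = 0
        n_rep = 1000
        for rep in range(n_rep):
            sample = generate_sample(SyntheticSpec(n=200, rho=rho, seed=900_000 + rep))
            tau = knight_tau(sample).tau
            low, high = confidence_interval(tau, 200, spec)
            covered += low <= true_tau <= high
        assert covered / n_rep >= 0.90


class TestPseudoR2:
    def test_perfect_fit(self):
        assert pseudo_r2([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_arcade_columns(self, arcade):
        assert pseudo_r2(arcade.x, arcade.y) == pytest.approx(
            0.8222222**2, abs=1e-6
        )

    def test_anti_monotone_fit_is_positive(self):
        assert pseudo_r2([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(1.0)

    def test_bounds(self, rng):
        for _ in range(10):
            v = pseudo_r2(rng.standard_normal(30), rng.standard_normal(30))
            assert 0.0 <= v <= 1.0
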