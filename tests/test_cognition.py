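import numpy as np
import pytest
from scipy import stats

from cogplast.cognition import (D2RLine, cohen_d_from_t, jn_ancova, jn_point_stat,
                                percent_gain, score_d2r, score_digit_span,
                                score_zvt, smm_critical_value,
                                welch_ci_from_summary, welch_test)


def line(processed=40, targets=20, commission=0, overlooked=0):
    return D2RLine(processed=processed, processed_targets=targets,
                   commission_errors=commission, overlooked_targets=overlooked)


class TestScoring:
    def test_d2r_literal_formula(self):
        lines = [line(targets=40, commission=3, overlooked=2, processed=47)]
        assert score_d2r(lines) == 35

    def test_d2r_zero_errors_is_target_count(self):
        lines = [line(targets=13) for _ in range(14)]
        assert score_d2r(lines) == 14 * 13

    def test_d2r_manual_convention_differs_by_overlooked(self):
        lines = [line(targets=40, commission=3, overlooked=2, processed=47)]
        assert score_d2r(lines, convention="manual") == 35  # 38 - 3
        lines2 = [line(targets=40, commission=0, overlooked=5, processed=47)]
        assert score_d2r(lines2) == 35
        assert score_d2r(lines2, convention="manual") == 35

    def test_d2r_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            score_d2r([line(processed=10, targets=12)])
        with pytest.raises(ValueError):
            score_d2r([line(processed=40, targets=20, commission=25)])

    def test_zvt_mean_of_four_forms(self):
        assert score_zvt([60, 62, 58, 64]) == pytest.approx(61.0)
        with pytest.raises(ValueError):
            score_zvt([60, 62, 58])

    def test_digit_span_counts_correct_trials(self):
        assert score_digit_span([True, False, True, True]) == 3

    def test_percent_gain(self):
        assert percent_gain(160, 176) == pytest.approx(10.0)
        assert percent_gain(5, 5) == 0.0
        pre = np.array([100.0, 200.0, 50.0])
        post = np.array([110.0, 180.0, 75.0])
        np.testing.assert_allclose(percent_gain(pre, post),
                                   [percent_gain(a, b) for a, b in zip(pre, post)])
        with pytest.raises(ValueError):
            percent_gain(0, 5)


class TestWelch:
    def test_derived_example(self):
        r = welch_test([1, 2, 3, 4], [2, 4, 6, 8])
        # direct formulas: t = -1.5/sqrt(5/3/4+...) with s1^2=5/3, s2^2=20/3
        se2 = (5 / 3) / 4 + (20 / 3) / 4
        t_oracle = (2.5 - 5.0) / np.sqrt(se2)
        df_oracle = se2 ** 2 / (((5 / 3) / 4) ** 2 / 3 + ((20 / 3) / 4) ** 2 / 3)
        assert r.t == pytest.approx(t_oracle, abs=1e-12)
        assert r.df == pytest.approx(df_oracle, abs=1e-10)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(1.0, 2.0, size=12)
        r = welch_test(x, y)
        t_sp, p_sp = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(t_sp, abs=1e-12)
        assert r.p == pytest.approx(p_sp, abs=1e-12)

    def test_identical_groups(self):
        r = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_reduces_to_pooled_t_for_equal_n_and_var(self, rng):
        x = rng.normal(size=16)
        y = rng.normal(size=16)
        # force equal sample variances by standardizing both groups
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1) + 0.4
        r = welch_test(x, y)
        t_pooled, _ = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(t_pooled, abs=1e-10)

    def test_published_effect_sizes_reproduced(self):
        # two-sample d = t * sqrt(1/n1 + 1/n2) at n = 32 vs 16
        assert cohen_d_from_t(0.42, 32, 16) == pytest.approx(0.13, abs=0.005)
        assert cohen_d_from_t(0.15, 32, 16) == pytest.approx(0.05, abs=0.005)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            welch_test([2.0, 2.0], [2.0, 2.0])


class TestWelchCIFromSummary:
    def test_reconstructs_published_interval(self):
        lo, hi = welch_ci_from_summary(-6.62, -2.35, 32.82)
        assert round(lo, 2) == -12.35
        assert round(hi, 2) == -0.89

    def test_zero_diff_symmetric(self):
        lo, hi = welch_ci_from_summary(0.0, 1.0, 20)
        assert lo == pytest.approx(-hi)

    def test_midpoint_is_mean_diff(self):
        lo, hi = welch_ci_from_summary(3.3, 2.1, 17.5)
        assert (lo + hi) / 2 == pytest.approx(3.3, abs=1e-10)

    def test_t_zero_rejected(self):
        with pytest.raises(ValueError):
            welch_ci_from_summary(1.0, 0.0, 10)


class TestSMM:
    def test_single_comparison_reduces_to_normal(self):
        assert smm_critical_value(1) == pytest.approx(1.96, abs=0.005)

    def test_k10(self):
        # numerically invert P(max |Z_k| <= c) = 0.95 under independence
        from scipy.optimize import brentq

        oracle = brentq(lambda c: (2 * stats.norm.cdf(c) - 1) ** 10 - 0.95, 1, 5)
        assert smm_critical_value(10) == pytest.approx(oracle, abs=1e-10)
        assert smm_critical_value(10) == pytest.approx(2.80, abs=0.005)

    def test_monotone_in_k(self):
        crits = [smm_critical_value(k) for k in range(1, 15)]
        assert np.all(np.diff(crits) > 0)


class TestJNAncova:
    def test_published_design_points_internally_consistent(self):
        stat, p = jn_point_stat(16.42, 23.12, 3.43)
        assert round(stat, 2) == -1.95
        assert round(p, 3) == 0.051
        stat2, _ = jn_point_stat(15.86, 21.80, 2.90)
        assert round(stat2, 2) == -2.05

    def test_identical_parallel_lines_give_null_stats(self, rng):
        n = 40
        x = rng.uniform(150, 220, n)
        y = 5.0 + 0.1 * x + rng.normal(0, 1.0, n)
        g = (np.arange(n) % 2 == 0).astype(int)
        res = jn_ancova(y, x, g, B=800, seed=5)
        assert np.all(np.abs(res.stat) < 3.0)
        assert not res.significant.any()

    def test_group_offset_recovered_at_design_points(self, rng):
        n = 120
        x = rng.uniform(0, 10, n)
        g = (np.arange(n) < 60).astype(int)
        delta = 2.5
        y = 1.0 + 0.5 * x + delta * g + rng.normal(0, 0.5, n)
        res = jn_ancova(y, x, g, B=800, seed=2)
        diffs = res.est_exercise - res.est_control
        assert np.all(np.abs(diffs - delta) < 0.5)
        assert res.significant.all()

    def test_stat_and_p_mutually_consistent(self, rng):
        n = 30
        x = rng.uniform(0, 5, n)
        y = x + rng.normal(size=n)
        g = (np.arange(n) % 3 == 0).astype(int)
        res = jn_ancova(y, x, g, B=500, seed=1)
        expected = 2 * stats.norm.sf(np.abs(res.stat))
        np.testing.assert_allclose(res.p, expected, atol=5e-4)

    def test_design_points_span_quartiles(self, rng):
        x = rng.uniform(100, 200, 50)
        y = rng.normal(size=50)
        g = (np.arange(50) % 2).astype(int)
        res = jn_ancova(y, x, g, n_points=10, B=500, seed=0)
        q25, q75 = np.percentile(x, [25, 75])
        assert res.design_points[0] == pytest.approx(q25)
        assert res.design_points[-1] == pytest.approx(q75)
        assert len(res.design_points) == 10

    def test_constant_covariate_rejected(self):
        g = np.array([0] * 6 + [1] * 6)
        x = np.where(g == 0, 1.0, np.arange(12, dtype=float))
        with pytest.raises(ValueError, match="constant"):
            jn_ancova(np.arange(12, dtype=float), x, g, B=500)
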