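import numpy as np
import pytest
from scipy import stats

from erpglm import (SubjectStack, one_sample_bootstrap_t, paired_percentile,
                    quantile_indices, regression_ci_indices,
                    regression_percentile, trimmed_mean, trimmed_mean_erp,
                    two_sample_percentile, welch_t)
from erpglm.level2_robust import draw_bootstrap_indices


class TestQuantileIndices:
    @pytest.mark.parametrize("alpha,B,expected", [
        (0.05, 1000, (25, 975)),
        (0.05, 599, (15, 584)),       # round(14.975) = 15
        (0.01, 100, (1, 99)),         # round(0.5) rounds half away from zero
    ])
    def test_values(self, alpha, B, expected):
        assert quantile_indices(alpha, B) == expected

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            quantile_indices(0.001, 100)

    @pytest.mark.parametrize("alpha,B,k,expected", [
        (0.05, 1000, 2, (13, 987)),   # round(1000*.05/4) = 13
        (0.05, 1000, 1, (25, 975)),
    ])
    def test_regression_bonferroni_rule(self, alpha, B, k, expected):
        assert regression_ci_indices(alpha, B, k) == expected

    @pytest.mark.parametrize("n,a", [(20, 6), (39, 6), (40, 7), (100, 10),
                                     (200, 13), (300, 15)])
    def test_simple_regression_lookup(self, n, a):
        got = regression_ci_indices(0.05, 599, 1, n_subjects=n)
        assert got == (a, 599 - a)


class TestOneSampleBootstrapT:
    def test_constant_zero_maps_degenerate(self):
        res = one_sample_bootstrap_t(SubjectStack(np.zeros((6, 2, 3))),
                                     n_boot=100, seed=0)
        assert res.ci.degenerate.all()
        assert np.all(res.ci.lower == 0) and np.all(res.ci.upper == 0)

    def test_ci_recomputed_from_stored_draws(self):
        # n=5, values 1..5 in a single cell
        x = np.arange(1.0, 6.0)[:, None, None]
        res = one_sample_bootstrap_t(SubjectStack(x), alpha=0.05, n_boot=200,
                                     seed=3, keep_boot=True)
        # hand-rolled recomputation from the saved T* vector
        m, s, n = x.mean(), x.std(ddof=1), 5
        t_sorted = np.sort(res.t_boot[:, 0, 0])
        L, U = quantile_indices(0.05, 200)
        lo = m - t_sorted[U - 1] * s / np.sqrt(n)
        hi = m - t_sorted[L - 1] * s / np.sqrt(n)
        assert res.ci.lower[0, 0] == pytest.approx(lo, abs=1e-12)
        assert res.ci.upper[0, 0] == pytest.approx(hi, abs=1e-12)
        # and the pivot draws really are (mean* - mean)/(s*/sqrt(n))
        b = 7
        draw = x[res.boot_indices[b], 0, 0]
        t_ref = (draw.mean() - m) / (draw.std(ddof=1) / np.sqrt(n))
        assert res.t_boot[b, 0, 0] == pytest.approx(t_ref, abs=1e-12)

    def test_shared_draws_across_cells(self, gaussian_stack):
        res = one_sample_bootstrap_t(gaussian_stack, n_boot=50, seed=1,
                                     keep_boot=True)
        assert res.boot_indices.shape == (50, gaussian_stack.n_subjects)

    def test_converges_to_student_ci_for_gaussian_data(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((25, 4, 5))
        res = one_sample_bootstrap_t(SubjectStack(x), alpha=0.05,
                                     n_boot=10_000, seed=12)
        se = x.std(axis=0, ddof=1) / np.sqrt(25)
        w_student = 2 * stats.t.ppf(0.975, 24) * se
        ratio = (res.ci.upper - res.ci.lower) / w_student
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_same_seed_bit_identical(self, gaussian_stack):
        a = one_sample_bootstrap_t(gaussian_stack, n_boot=300, seed=5)
        b = one_sample_bootstrap_t(gaussian_stack, n_boot=300, seed=5)
        assert np.array_equal(a.ci.lower, b.ci.lower)
        assert np.array_equal(a.statmap.p_uncorrected, b.statmap.p_uncorrected)


class TestTwoSamplePercentile:
    def test_welch_textbook_fixture(self):
        sm = welch_t(np.array([1.0, 2, 3, 4])[:, None, None],
                     np.array([2.0, 4, 6, 8])[:, None, None])
        v1 = np.var([1, 2, 3, 4], ddof=1)
        v2 = np.var([2, 4, 6, 8], ddof=1)
        t_ref = (2.5 - 5.0) / np.sqrt(v1 / 4 + v2 / 4)
        df_ref = (v1 / 4 + v2 / 4) ** 2 / ((v1 / 4) ** 2 / 3 + (v2 / 4) ** 2 / 3)
        assert sm.stat[0, 0] == pytest.approx(t_ref, abs=1e-12)
        assert sm.df[1] == pytest.approx(df_ref, abs=1e-9)

    def test_identical_zero_groups(self):
        z = SubjectStack(np.zeros((5, 2, 2)))
        res = two_sample_percentile(z, SubjectStack(np.zeros((4, 2, 2))),
                                    n_boot=100, seed=0)
        assert np.all(res.difference == 0)
        assert np.all(res.ci.lower == 0) and np.all(res.ci.upper == 0)
        assert not res.significant.any()

    def test_constant_shift_sign(self):
        c = 3.0 * np.ones((6, 2, 2))
        res = two_sample_percentile(SubjectStack(c), SubjectStack(c + 2.0),
                                    n_boot=100, seed=0)
        assert np.all(res.difference == -2.0)
        assert np.all(res.ci.lower == -2.0) and np.all(res.ci.upper == -2.0)

    def test_group_reversal_mirrors_ci(self, rng):
        a = SubjectStack(rng.normal(size=(9, 2, 3)))
        b = SubjectStack(rng.normal(0.5, size=(9, 2, 3)))
        r1 = two_sample_percentile(a, b, n_boot=2000, seed=7, keep_boot=True)
        r2 = two_sample_percentile(b, a, n_boot=2000, seed=7)
        assert np.allclose(r1.difference, -r2.difference)
        # exact mirror on a shared bootstrap distribution: negating D* maps
        # D_(U) -> -D_(L+1) because B + 1 - U = L + 1
        L, U = quantile_indices(0.05, 2000)
        neg_sorted = np.sort(-r1.d_boot, axis=0)
        assert np.allclose(-r1.ci.upper, neg_sorted[L], atol=1e-12)
        assert np.allclose(-r1.ci.lower, neg_sorted[U - 1], atol=1e-12)
        # across independent index draws the mirror holds to resampling noise
        assert np.allclose(r1.ci.lower, -r2.ci.upper, atol=0.35)
        assert np.allclose(r1.ci.upper, -r2.ci.lower, atol=0.35)

    def test_p_clipped_to_unit_interval(self, rng):
        a = SubjectStack(rng.normal(size=(8, 2, 3)))
        b = SubjectStack(rng.normal(5.0, size=(8, 2, 3)))
        res = two_sample_percentile(a, b, n_boot=200, seed=1)
        assert np.all(res.p >= 1 / 200) and np.all(res.p <= 1)
        assert res.significant.all()


class TestPairedPercentile:
    def test_identical_stacks_zero_difference(self, rng):
        x = SubjectStack(rng.normal(size=(8, 2, 3)))
        y = SubjectStack(x.maps.copy())
        res = paired_percentile(x, y, n_boot=100, seed=0)
        assert np.all(res.difference == 0)
        assert not res.significant.any()

    def test_unit_shift_detected(self, rng):
        x = SubjectStack(rng.normal(size=(8, 2, 3)))
        y = SubjectStack(x.maps + 1.0)
        res = paired_percentile(x, y, n_boot=1000, seed=0)
        assert np.allclose(res.difference, -1.0)
        assert res.significant.all()

    def test_mismatched_subjects_rejected(self, rng):
        x = SubjectStack(rng.normal(size=(6, 2, 2)), subject_ids=list("abcdef"))
        y = SubjectStack(rng.normal(size=(6, 2, 2)), subject_ids=list("abcdeg"))
        with pytest.raises(ValueError, match="subjects"):
            paired_percentile(x, y)

    def test_equals_one_sample_percentile_on_differences(self, rng):
        """Joint pair resampling is exactly the percentile bootstrap of the
        mean of the subject-wise differences under the same index draws."""
        x = SubjectStack(rng.normal(size=(10, 2, 3)))
        y = SubjectStack(x.maps + rng.normal(0.3, 0.5, size=(10, 2, 3)))
        res = paired_percentile(x, y, n_boot=300, seed=42, keep_boot=True)
        d = x.maps - y.maps
        idx = draw_bootstrap_indices(np.random.default_rng(42), 10, 300)
        d_boot_ref = d[idx].mean(axis=1)
        assert np.allclose(res.d_boot, d_boot_ref, atol=1e-12)
        ds = np.sort(d_boot_ref, axis=0)
        L, U = quantile_indices(0.05, 300)
        assert np.allclose(res.ci.lower, ds[L], atol=1e-12)
        assert np.allclose(res.ci.upper, ds[U - 1], atol=1e-12)
        pos = (d_boot_ref > 0).mean(axis=0)
        p_ref = np.clip(2 * np.minimum(pos, 1 - pos), 1 / 300, 1)
        assert np.allclose(res.p, p_ref, atol=1e-12)


class TestRegressionPercentile:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=12)
        maps = 2.0 * x[:, None, None] * np.ones((12, 2, 3))
        res = regression_percentile(SubjectStack(maps), x, seed=0)
        assert np.allclose(res.slopes, 2.0, atol=1e-10)
        assert res.significant.all()

    def test_constant_maps_not_significant(self, rng):
        maps = np.ones((12, 2, 2)) * 5.0
        res = regression_percentile(SubjectStack(maps), rng.normal(size=12),
                                    seed=0)
        assert np.allclose(res.slopes, 0.0, atol=1e-12)
        assert not res.significant.any()

    def test_default_simple_regression_uses_599(self, rng):
        res = regression_percentile(SubjectStack(rng.normal(size=(20, 2, 2))),
                                    rng.normal(size=20), seed=1)
        assert res.n_boot == 599
        assert (res.index_low, res.index_high) == (7, 593)   # a=6, c=593

    def test_rank_deficient_predictors_rejected(self, rng):
        P = np.ones((10, 2))
        P[:, 1] = 2.0   # collinear with each other and the intercept
        with pytest.raises(ValueError):
            regression_percentile(SubjectStack(rng.normal(size=(10, 2, 2))), P)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            regression_percentile(SubjectStack(rng.normal(size=(3, 2, 2))),
                                  rng.normal(size=(3, 2)))


class TestTrimmedMean:
    def test_values_one_to_ten(self):
        assert trimmed_mean(np.arange(1.0, 11.0), 0.2) == pytest.approx(5.5)

    def test_trim_zero_is_plain_mean(self, rng):
        x = rng.normal(size=(11, 2))
        assert np.allclose(trimmed_mean(x, 0.0), x.mean(axis=0))

    def test_all_equal_degenerate_ci(self):
        maps = np.full((10, 2, 2), 7.0)
        est, ci = trimmed_mean_erp(maps, seed=0)
        assert np.all(est == 7.0)
        assert np.all(ci.lower == 7.0) and np.all(ci.upper == 7.0)

    def test_excessive_trim_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean(np.arange(10.0), 0.5)
        with pytest.raises(ValueError, match="small"):
            trimmed_mean_erp(np.ones((4, 1, 1)), trim=0.5)

    def test_bootstrap_se_ci_brackets_estimate(self, rng):
        maps = rng.normal(size=(20, 2, 3))
        est, ci = trimmed_mean_erp(maps, seed=5)
        assert np.all(ci.lower <= est) and np.all(est <= ci.upper)


class TestQuantileIndexProperties:
    def test_hypothesis_invariants(self):
        """L and U bracket the central (1 - alpha) mass symmetrically:
        L >= 1, U = B - L, and L is within half a step of alpha*B/2."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, derandomize=True)
        @given(alpha=st.floats(0.005, 0.4), B=st.integers(100, 5000))
        def check(alpha, B):
            if alpha * B < 1.0:      # L would round to 0: contract error
                with pytest.raises(ValueError):
                    quantile_indices(alpha, B)
                return
            L, U = quantile_indices(alpha, B)
            assert 1 <= L < U <= B
            assert U == B - L
            assert abs(L - alpha * B / 2.0) <= 0.5

        check()
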