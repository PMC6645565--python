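import math

import numpy as np
import pytest
from scipy import stats

from deconcord import (
    EnrichmentResult,
    exact_multi_overlap_pmf,
    expected_overlap,
    fold_summary,
    hypergeom_tail,
    null_overlap_samples,
    permutation_test,
    read_report,
    sample_null_overlap,
    write_report,
)


class TestExpectedOverlap:
    @pytest.mark.parametrize(
        "sizes, N, expected",
        [((100, 200), 1000, 20.0), ((50, 50), 500, 5.0), ((10, 10, 10), 100, 0.1)],
    )
    def test_closed_form(self, sizes, N, expected):
        assert expected_overlap(sizes, N) == pytest.approx(expected)

    def test_full_set_forces_other(self):
        assert expected_overlap((200, 37), 200) == pytest.approx(37.0)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap((11,), 10)


class TestNullSampling:
    def test_full_sets_always_fully_overlap(self):
        rng = np.random.default_rng(0)
        assert sample_null_overlap((5, 5), 5, rng) == 5

    @pytest.mark.parametrize(
        "sizes, N, mean",
        [((1, 1), 2, 0.5), ((2, 2), 4, 1.0)],
    )
    def test_long_run_mean_matches_closed_form(self, sizes, N, mean):
        rng = np.random.default_rng(1)
        draws = null_overlap_samples(sizes, N, 20_000, rng, method="sets")
        # exact hypergeometric variance gives the SE of the mean
        n, K = sizes
        var = n * K / N * (N - K) / N * (N - n) / (N - 1)
        se = math.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 4 * se

    def test_fast_path_matches_set_sampling_distribution(self):
        # same null, two samplers: chi-square homogeneity on pooled bins
        for sizes, N in [((3, 4), 10), ((2, 3, 4), 8)]:
            a = null_overlap_samples(sizes, N, 4000,
                                     np.random.default_rng(2), method="sets")
            b = null_overlap_samples(sizes, N, 4000,
                                     np.random.default_rng(3),
                                     method="hypergeometric")
            top = min(sizes)
            fa = np.bincount(a, minlength=top + 1)
            fb = np.bincount(b, minlength=top + 1)
            keep = (fa + fb) >= 10
            chi2 = stats.chi2_contingency(np.vstack([fa[keep], fb[keep]]))
            assert chi2.pvalue > 1e-3

    def test_zero_size_set_gives_zero_overlap(self):
        rng = np.random.default_rng(4)
        draws = null_overlap_samples((0, 5), 10, 100, rng)
        assert (draws == 0).all()


class TestFoldSummary:
    def test_constant_fold(self):
        assert fold_summary(20, [10] * 7) == (2.0, 2.0, 2.0, 0)

    def test_median_is_middle_order_statistic(self):
        med, q05, q95, zeros = fold_summary(10, [1, 2, 4, 5, 10])
        assert med == 2.5 and q05 == 1.0 and q95 == 10.0 and zeros == 0

    def test_zero_denominator_convention(self):
        # folds {5, +inf}: lower empirical median is the finite one
        med, _, q95, zeros = fold_summary(5, [0, 1])
        assert med == 5.0 and math.isinf(q95) and zeros == 1

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            fold_summary(1, [])


class TestPermutationTest:
    def test_observed_zero_gives_p_one(self):
        res = permutation_test(0, (5, 5), 100, B=200, seed=0)
        assert res.p_value == 1.0

    def test_minimum_p_when_observed_unattainable_by_null(self):
        res = permutation_test(20, (20, 20), 10_000, B=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_observed_above_smallest_set_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(6, (5, 9), 100, B=10, seed=0)

    def test_determinism(self):
        a = permutation_test(3, (30, 40), 500, B=2000, seed=11)
        b = permutation_test(3, (30, 40), 500, B=2000, seed=11)
        assert a == b

    def test_p_non_increasing_in_observed(self):
        ps = [
            permutation_test(obs, (30, 40), 500, B=2000, seed=11).p_value
            for obs in range(0, 10)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(1 / 2001 <= p <= 1 for p in ps)

    def test_matches_exact_hypergeometric_tail(self):
        sizes, N, B = (2, 2), 4, 20_000
        res = permutation_test(2, sizes, N, B=B, seed=5)
        p_exact = hypergeom_tail(2, 2, 2, 4)
        assert p_exact == pytest.approx(1 / 6)
        mc_err = 4 * math.sqrt(p_exact * (1 - p_exact) / B) + 1 / B
        assert abs(res.p_value - p_exact) < mc_err

    def test_result_roundtrips_through_report(self, tmp_path):
        res = permutation_test(40, (50, 60), 200, B=500, seed=3)
        path = tmp_path / "enrich.json"
        write_report(res, path)
        assert read_report(path) == res

    def test_inconsistent_result_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentResult(
                observed_overlap=1, set_sizes=(2, 2), universe_size=10,
                B=100, seed=0, ge_count=5, p_value=0.5,
                expected_overlap=0.4, fold_median=1.0, fold_q05=1.0,
                fold_q95=1.0, zero_overlap_samples=0,
            )


class TestExactOracles:
    @pytest.mark.parametrize("obs, expected", [(0, 1.0), (1, 0.5)])
    def test_singleton_tail(self, obs, expected):
        assert hypergeom_tail(obs, 1, 1, 2) == pytest.approx(expected)

    def test_forced_overlap_pmf(self):
        assert exact_multi_overlap_pmf((4, 4, 4), 4) == {0: 0, 1: 0, 2: 0, 3: 0, 4: 1.0}

    def test_three_singletons(self):
        pmf = exact_multi_overlap_pmf((1, 1, 1), 2)
        assert pmf[0] == pytest.approx(3 / 4)
        assert pmf[1] == pytest.approx(1 / 4)

    def test_k2_convolution_reproduces_hypergeometric_pmf(self):
        n1, n2, N = 5, 7, 15
        pmf = exact_multi_overlap_pmf((n1, n2), N)
        for t, p in pmf.items():
            assert p == pytest.approx(stats.hypergeom.pmf(t, N, n1, n2), abs=1e-12)

    def test_enumeration_matches_convolution_k3(self):
        sizes, N = (3, 4, 2), 7
        conv = exact_multi_overlap_pmf(sizes, N)
        enum = exact_multi_overlap_pmf(sizes, N, method="enumerate")
        for t in conv:
            assert conv[t] == pytest.approx(enum[t], abs=1e-12)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="permutation_test"):
            exact_multi_overlap_pmf((500, 500), 5000, method="enumerate")

    def test_pmf_sums_to_one(self):
        pmf = exact_multi_overlap_pmf((6, 8, 5, 7), 20)
        assert sum(pmf.values()) == pytest.approx(1.0)
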