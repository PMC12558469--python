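"""Downsampling, Gini clonality and the rank/regression comparisons."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tcrep.diversity import (
    DownsampleError,
    downsample,
    fit_group_age_model,
    gini,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from tcrep.io import Repertoire


def gini_pairwise_oracle(x):
    """O(n^2) population Gini: sum |xi - xj| / (2 n^2 mean)."""
    x = np.asarray(x, dtype=float)
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2 * x.mean())


class TestGini:
    def test_perfect_evenness_is_zero(self):
        assert gini([1, 1, 1, 1]) == 0.0

    def test_three_one_equals_one_quarter(self):
        assert gini([3, 1]) == pytest.approx(0.25, abs=1e-15)

    def test_sorted_form_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(1, 1000, size=rng.integers(1, 100))
            assert gini(x) == pytest.approx(gini_pairwise_oracle(x), abs=1e-12)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=50),
           st.integers(1, 20))
    def test_scale_invariance(self, counts, c):
        assert gini(counts) == pytest.approx(gini(np.array(counts) * c), abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gini([3, 0, 1])


class TestDownsample:
    def test_full_draw_is_identity(self):
        rep = Repertoire.from_counts("s", {"A": 5, "B": 5})
        assert downsample(rep, 10, seed=0).counts() == {"A": 5, "B": 5}

    def test_target_above_total_errors_naming_sample(self):
        rep = Repertoire.from_counts("tiny", {"A": 5})
        with pytest.raises(DownsampleError, match="tiny"):
            downsample(rep, 6, seed=0)

    def test_output_total_always_equals_target(self):
        rng = np.random.default_rng(1)
        for seed in range(20):
            counts = {f"S{i}": int(c) for i, c in enumerate(rng.integers(1, 50, 12))}
            rep = Repertoire.from_counts("s", counts)
            target = int(rng.integers(1, rep.total_templates + 1))
            assert downsample(rep, target, seed=seed).total_templates == target

    def test_hypergeometric_mean_within_3_se_over_500_seeds(self):
        rep = Repertoire.from_counts("s", {"A": 90, "B": 10})
        draws = [downsample(rep, 10, seed=s).counts().get("A", 0) for s in range(500)]
        # hypergeometric: mean 9, var = 10 * .9 * .1 * (90/99)
        se = np.sqrt(10 * 0.9 * 0.1 * (90 / 99) / 500)
        assert abs(np.mean(draws) - 9.0) < 3 * se


class TestRankTests:
    def test_rank_sum_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_rank_sum_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_rank_sum_exact_vs_normal_agree_at_n15(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(0.3, size=15)
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(exact - approx) < 0.01
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(approx, abs=1e-12)  # n=30 -> asymptotic branch

    def test_signed_rank_all_positive(self):
        _, p = wilcoxon_signed_rank([1, 2, 3])
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_signed_rank_symmetric_pair(self):
        _, p = wilcoxon_signed_rank([-1, 1])
        assert p == 1.0

    def test_signed_rank_exact_vs_normal_agree_at_n14(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, size=14)
        exact = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        approx = stats.wilcoxon(d, alternative="two-sided", method="approx",
                                correction=True).pvalue
        assert abs(exact - approx) < 0.05
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(exact, abs=1e-12)

    def test_all_zero_differences_p_one(self):
        assert wilcoxon_signed_rank([0.0, 0.0])[1] == 1.0


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 5, size=30).astype(float)
            y = rng.integers(0, 5, size=30).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestGroupAgeModel:
    def test_exact_linear_fit_recovers_coefficients(self):
        age = np.arange(40, 80, dtype=float)
        y = 0.2 + 0.001 * age
        group = ["healthy", "MM"] * 20
        fit = fit_group_age_model(y, age, group)
        assert fit.params["age"] == pytest.approx(0.001, abs=1e-10)
        # with a zero-residual fit the group effect is zero to rounding; its
        # t-test is 0/0 in floating point, so assert the coefficient itself
        assert abs(fit.params["group[MM]"]) < 1e-10

    def test_slope_ci_coverage(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            age = rng.uniform(40, 80, 200)
            group = np.where(rng.random(200) < 0.5, "healthy", "MM")
            y = 0.3 + 0.002 * age + rng.normal(0, 0.01, 200)
            fit = fit_group_age_model(y, age, group)
            half = 1.96 * fit.bse["age"]
            if abs(fit.params["age"] - 0.002) <= half:
                hits += 1
        assert hits >= 93

    def test_rank_deficient_design_names_columns(self):
        age = np.full(30, 60.0)  # constant age == intercept
        y = np.linspace(0, 1, 30)
        group = ["healthy", "MM"] * 15
        with pytest.raises(ValueError, match="age"):
            fit_group_age_model(y, age, group)

    def test_permuted_group_labels_have_uniformish_p(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            age = rng.uniform(40, 80, 80)
            y = 0.3 + 0.002 * age + rng.normal(0, 0.02, 80)
            group = rng.permutation(["healthy"] * 40 + ["MM"] * 40)
            ps.append(fit_group_age_model(y, age, group).pvalues["group[MM]"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
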