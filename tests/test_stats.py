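"""Exact rank tests against brute-force enumeration oracles and scipy."""

import math
from itertools import combinations, product

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from uspioquant.phantom import CohortSamplers, GroupSummarySampler, simulate_cohort
from uspioquant.stats import (
    cohort_compare, mann_whitney_exact, median_iqr, wilcoxon_signed_rank_exact,
)


def naive_mann_whitney_p(x, y):
    """Oracle: literal enumeration of every group assignment of the mid-ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * rankdata(pooled)).astype(int)
    r_obs = int(ranks2[:nx].sum())
    le = ge = total = 0
    for idx in combinations(range(len(pooled)), nx):
        s = sum(int(ranks2[i]) for i in idx)
        total += 1
        le += s <= r_obs
        ge += s >= r_obs
    return min(1.0, 2.0 * min(le, ge) / total)


def naive_wilcoxon_p(diffs):
    """Oracle: literal enumeration of all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks2 = np.rint(2 * rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    le = ge = total = 0
    for signs in product([0, 1], repeat=len(d)):
        w = int(sum(r for r, s in zip(ranks2, signs) if s))
        total += 1
        le += w <= w_obs
        ge += w >= w_obs
    return min(1.0, 2.0 * min(le, ge) / total)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney_exact([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.p_value == 1.0
        assert res.has_ties

    def test_complete_separation_9_vs_6(self):
        """Disjoint groups at the study sizes give the minimal p, 2/5005."""
        res = mann_whitney_exact(np.arange(9) + 100.0, np.arange(6) + 1.0)
        assert res.exact
        assert res.p_value == pytest.approx(2.0 / 5005.0, rel=1e-12)
        assert res.p_value == pytest.approx(2 * math.factorial(9) * math.factorial(6)
                                            / math.factorial(15), rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_with_ties(self, seed):
        """Exact p equals the literal-enumeration oracle on tied integer data."""
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 6, 2)
        x = rng.integers(0, 4, nx).astype(float)
        y = rng.integers(0, 4, ny).astype(float)
        assert mann_whitney_exact(x, y).p_value == pytest.approx(
            naive_mann_whitney_p(x, y), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed + 100)
        x, y = rng.normal(0, 1, 8), rng.normal(0.8, 1, 7)
        assert mann_whitney_exact(x, y).p_value == pytest.approx(
            mannwhitneyu(x, y, method="exact").pvalue, rel=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 1, 6)
        assert mann_whitney_exact(x, y).p_value == mann_whitney_exact(y, x).p_value

    def test_p_monotone_in_group_separation(self):
        base = np.linspace(0, 1, 6)
        p_prev = 1.1
        for shift in (0.0, 0.5, 1.5, 5.0):
            p = mann_whitney_exact(base + shift, base).p_value
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_large_groups_fall_back_to_seeded_permutation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(3, 1, 16), rng.normal(0, 1, 15)  # C(31,16) > 1e6
        res = mann_whitney_exact(x, y, seed=1)
        assert not res.exact
        assert res.permutation_seed == 1
        assert res.p_value < 0.001
        again = mann_whitney_exact(x, y, seed=1)
        assert res.p_value == again.p_value


class TestWilcoxon:
    def test_antisymmetric_differences_p_one(self):
        res = wilcoxon_signed_rank_exact([2.0, -2.0, 1.0, -1.0])
        assert res.p_value == 1.0

    def test_all_nine_positive_differences(self):
        """Nine same-sign differences give the doubled one-tail minimum, 2/512."""
        res = wilcoxon_signed_rank_exact(np.arange(1, 10) + 0.1)
        assert res.exact
        assert res.p_value == pytest.approx(2.0 / 512.0, rel=1e-12)

    def test_paired_interface_drops_zero_differences(self):
        x = np.array([5.0, 4.0, 7.0, 3.0])
        y = np.array([5.0, 2.0, 3.0, 1.0])  # first pair ties out
        res = wilcoxon_signed_rank_exact(x, y)
        assert res.n == (3,)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([0.0, 0.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = rng.integers(-3, 4, n).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        assert wilcoxon_signed_rank_exact(d).p_value == pytest.approx(
            naive_wilcoxon_p(d), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed + 50)
        d = rng.normal(0.5, 1, 10)
        assert wilcoxon_signed_rank_exact(d).p_value == pytest.approx(
            wilcoxon(d, mode="exact").pvalue, rel=1e-12)


class TestMedianIqr:
    def test_linear_interpolation_convention(self):
        s = median_iqr([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)

    def test_single_value(self):
        s = median_iqr([7.5])
        assert (s.q1, s.median, s.q3) == (7.5, 7.5, 7.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_recovers_sampler_median(self):
        from uspioquant.phantom import sample_two_piece
        draws = sample_two_piece(GroupSummarySampler(1.12, 1.24, 1.36), 100_000, 8)
        assert median_iqr(draws).median == pytest.approx(1.24, abs=0.02)


class TestCohortCompare:
    def test_default_cohort_headline_comparison_significant(self):
        records = simulate_cohort(9, 6, seed=0)
        comp = cohort_compare(records, measure="indexed_to_native",
                              comparison="allo_vs_iso_unpaired")
        assert comp.result.exact
        assert comp.result.p_value < 0.01
        assert comp.summaries["allograft"].median > comp.summaries["isograft"].median

    def test_paired_graft_vs_native_within_allografts(self):
        records = simulate_cohort(9, 6, seed=0)
        comp = cohort_compare(records, comparison="graft_vs_native_paired",
                              group="allograft")
        assert comp.result.method == "wilcoxon-signed-rank"
        assert comp.result.n == (9,)

    def test_flagged_records_excluded_and_counted(self):
        records = simulate_cohort(5, 5, seed=1)
        records[0].flags.append("synthetic flag")
        comp = cohort_compare(records, comparison="allo_vs_iso_unpaired")
        assert comp.n_excluded == 1
        assert comp.result.n == (4, 5)

    def test_insufficient_animals_rejected(self):
        records = simulate_cohort(2, 2, seed=0)
        with pytest.raises(ValueError, match="too few"):
            cohort_compare(records, comparison="allo_vs_iso_unpaired")

    def test_type_one_error_calibrated_under_null(self):
        """With both groups drawn from one sampler, rejections at 0.05 stay nominal."""
        sampler = GroupSummarySampler(0.9, 1.1, 1.4)
        rng = np.random.default_rng(12345)
        n_cohorts, rejections = 2000, 0
        for _ in range(n_cohorts):
            x = sampler.sample(9, rng)
            y = sampler.sample(6, rng)
            rejections += mann_whitney_exact(x, y).p_value < 0.05
        rate = rejections / n_cohorts
        # exact test is conservative: rate must not exceed the binomial upper
        # bound at nominal 0.05 and must show reasonable power to reject
        ci_half = 3 * np.sqrt(0.05 * 0.95 / n_cohorts)
        assert rate <= 0.05 + ci_half
        assert rate >= 0.01

    def test_null_samplers_mostly_nonsignificant(self):
        """Isograft sampler == allograft sampler kills the group difference."""
        ref = CohortSamplers.reference()
        null = CohortSamplers(
            indexed_to_native={g: ref.indexed_to_native["allograft"]
                               for g in ("allograft", "isograft")},
            indexed_to_muscle=ref.indexed_to_muscle,
            native_delta=ref.native_delta, baseline=ref.baseline,
        )
        n_sig = 0
        for seed in range(20):
            records = simulate_cohort(9, 6, samplers=null, seed=seed)
            comp = cohort_compare(records, measure="indexed_to_native",
                                  comparison="allo_vs_iso_unpaired")
            n_sig += comp.significant
        assert n_sig <= 4
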