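"""Exact small-sample nonparametric inference for transplant cohorts.

With group sizes of nine and six, normal approximations to rank-test nulls
are unreliable, so both tests enumerate their permutation null completely:

* Mann-Whitney U (unpaired, isograft vs allograft): all C(n1+n2, n1)
  assignments of the pooled mid-ranks to groups;
* Wilcoxon matched-pairs signed rank (graft vs native kidney): all 2^n
  sign assignments of the nonzero-difference ranks.

Ties are handled with mid-ranks and the null is enumerated on the observed
(tied) rank configuration, which preserves exactness under ties.  Two-sided
p-values use the doubling convention, ``min(1, 2 * min(P(T <= t), P(T >= t)))``.
When enumeration would be too large, a seeded Monte-Carlo permutation null
is substituted and flagged in the result; it is never used silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .roi import GRAFT, NATIVE, AnimalRecord

__all__ = [
    "TestResult",
    "GroupSummary",
    "mann_whitney_exact",
    "wilcoxon_signed_rank_exact",
    "median_iqr",
    "cohort_compare",
    "CohortComparison",
]

MAX_ENUMERATION = 1_000_000
MAX_WILCOXON_N = 20
N_PERMUTATIONS = 100_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one exact (or seeded-permutation) rank test."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    exact: bool
    has_ties: bool
    permutation_seed: int | None = None

    @property
    def significant(self) -> bool:
        """Two-sided significance at the study's alpha = 0.05."""
        return self.p_value < 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Median and interquartile range, linear-interpolation convention."""

    n: int
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        return f"{self.median:.2f} ({self.q1:.2f} to {self.q3:.2f}), n={self.n}"


def median_iqr(values: np.ndarray | list[float]) -> GroupSummary:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return GroupSummary(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def _two_sided_p(count_le: int, count_ge: int, total: int) -> float:
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def _rank_sum_distribution(ranks2: np.ndarray, k: int) -> np.ndarray:
    """Exact null distribution of the doubled rank sum over all k-subsets.

    Dynamic programme over the generating function
    prod_i (1 + z * x^{r_i}): ``out[s]`` counts the k-subsets of ``ranks2``
    summing to s.  Equivalent to complete enumeration of the C(n, k) group
    assignments, including under mid-rank ties.
    """
    max2 = int(ranks2.sum())
    table = np.zeros((k + 1, max2 + 1))
    table[0, 0] = 1.0
    for r2 in ranks2:
        r2 = int(r2)
        for kk in range(k, 0, -1):  # descending: each rank used at most once
            table[kk, r2:] += table[kk - 1, : max2 + 1 - r2]
    return table[k]


def mann_whitney_exact(x: np.ndarray | list[float], y: np.ndarray | list[float],
                       seed: int = 0) -> TestResult:
    """Exact two-sided Mann-Whitney test by complete enumeration.

    The U statistic is computed from pooled mid-ranks.  When
    C(n1+n2, n1) <= 1e6 the null is enumerated completely; otherwise a
    seeded permutation null with 1e5 resamples is used and marked inexact.
    Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    nx, ny = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    # mid-ranks are multiples of 1/2; doubling makes all arithmetic integral
    ranks2 = np.rint(2.0 * rankdata(pooled)).astype(np.int64)
    has_ties = np.unique(pooled).size < pooled.size

    r_obs2 = int(ranks2[:nx].sum())  # 2 * (rank sum of x)
    n_total = nx + ny
    n_combos = math.comb(n_total, nx)

    if n_combos <= MAX_ENUMERATION:
        dist = _rank_sum_distribution(ranks2, nx)
        count_le = float(dist[: r_obs2 + 1].sum())
        count_ge = float(dist[r_obs2:].sum())
        p = min(1.0, 2.0 * min(count_le, count_ge) / n_combos)
        exact, perm_seed = True, None
    else:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((N_PERMUTATIONS, n_total)), axis=1)[:, :nx]
        sums2 = ranks2[order].sum(axis=1)
        count_le = int(np.count_nonzero(sums2 <= r_obs2)) + 1
        count_ge = int(np.count_nonzero(sums2 >= r_obs2)) + 1
        p = _two_sided_p(count_le, count_ge, N_PERMUTATIONS + 1)
        exact, perm_seed = False, seed

    u_stat = r_obs2 / 2.0 - nx * (nx + 1) / 2.0
    return TestResult(statistic=float(u_stat), p_value=float(p), n=(nx, ny),
                      method="mann-whitney", exact=exact, has_ties=bool(has_ties),
                      permutation_seed=perm_seed)


def wilcoxon_signed_rank_exact(x: np.ndarray | list[float],
                               y: np.ndarray | list[float] | None = None,
                               seed: int = 0) -> TestResult:
    """Exact two-sided Wilcoxon matched-pairs signed rank test.

    Accepts paired samples (x, y) or precomputed differences (y omitted).
    Zero differences are dropped; tied magnitudes receive mid-ranks.  The
    null enumerates all 2^n sign assignments (n <= 20) via the generating
    function of the signed-rank sum; larger n falls back to a seeded
    permutation null.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; the test is undefined")
    n = int(d.size)
    ranks2 = np.rint(2.0 * rankdata(np.abs(d))).astype(np.int64)
    has_ties = np.unique(np.abs(d)).size < d.size
    w_obs2 = int(ranks2[d > 0].sum())  # 2 * W+

    if n <= MAX_WILCOXON_N:
        # distribution of 2*W+ over all sign vectors, by polynomial product
        max2 = int(ranks2.sum())
        counts = np.zeros(max2 + 1, dtype=np.float64)
        counts[0] = 1.0
        for r2 in ranks2:
            shifted = np.zeros_like(counts)
            shifted[r2:] = counts[: max2 + 1 - r2]
            counts = counts + shifted
        total = counts.sum()  # == 2^n
        count_le = counts[: w_obs2 + 1].sum()
        count_ge = counts[w_obs2:].sum()
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        exact, perm_seed = True, None
    else:
        rng = np.random.default_rng(seed)
        signs = rng.random((N_PERMUTATIONS, n)) < 0.5
        sums2 = (signs * ranks2).sum(axis=1)
        count_le = int(np.count_nonzero(sums2 <= w_obs2)) + 1
        count_ge = int(np.count_nonzero(sums2 >= w_obs2)) + 1
        p = _two_sided_p(count_le, count_ge, N_PERMUTATIONS + 1)
        exact, perm_seed = False, seed

    return TestResult(statistic=w_obs2 / 2.0, p_value=float(p), n=(n,),
                      method="wilcoxon-signed-rank", exact=exact,
                      has_ties=bool(has_ties), permutation_seed=perm_seed)


@dataclass(frozen=True)
class CohortComparison:
    """A cohort-level test plus the per-group summaries it compared."""

    result: TestResult
    summaries: dict[str, GroupSummary]
    measure: str
    comparison: str
    n_excluded: int

    @property
    def significant(self) -> bool:
        return self.result.significant


def _measure_values(record: AnimalRecord, measure: str) -> float | None:
    if measure == "indexed_to_native":
        return record.indexed_to_native
    if measure == "indexed_to_muscle":
        return record.indexed_to_muscle.get(GRAFT)
    if measure.startswith("delta:"):
        tissue = measure.split(":", 1)[1]
        if tissue not in record.tissues:
            return None
        return record.delta(tissue)
    raise ValueError(f"unknown measure {measure!r}")


def cohort_compare(records: list[AnimalRecord], measure: str = "indexed_to_native",
                   comparison: str = "allo_vs_iso_unpaired",
                   group: str = "allograft", min_animals: int = 3,
                   seed: int = 0) -> CohortComparison:
    """Dispatch a cohort measure to the appropriate exact test.

    ``allo_vs_iso_unpaired`` compares the measure between transplant groups
    with the exact Mann-Whitney test; ``graft_vs_native_paired`` compares
    graft vs native-kidney deltaR2* within one group with the exact
    Wilcoxon signed-rank test.  Flagged records (and records lacking the
    measure) are excluded and counted in ``n_excluded``.
    """
    usable = [r for r in records if not r.flagged]
    if comparison == "allo_vs_iso_unpaired":
        groups: dict[str, list[float]] = {"allograft": [], "isograft": []}
        excluded = len(records) - len(usable)
        for r in usable:
            v = _measure_values(r, measure)
            if v is None:
                excluded += 1
            elif r.group in groups:
                groups[r.group].append(v)
        if min(len(groups["allograft"]), len(groups["isograft"])) < min_animals:
            raise ValueError("too few unflagged animals for the unpaired comparison")
        result = mann_whitney_exact(groups["allograft"], groups["isograft"], seed=seed)
        summaries = {g: median_iqr(v) for g, v in groups.items()}
        return CohortComparison(result, summaries, measure,
                                comparison, excluded)

    if comparison == "graft_vs_native_paired":
        graft_d, native_d = [], []
        in_group = [r for r in records if r.group == group]
        for r in in_group:
            if r.flagged or GRAFT not in r.tissues or NATIVE not in r.tissues:
                continue
            graft_d.append(r.delta(GRAFT))
            native_d.append(r.delta(NATIVE))
        if len(graft_d) < min_animals:
            raise ValueError("too few unflagged animals for the paired comparison")
        result = wilcoxon_signed_rank_exact(graft_d, native_d, seed=seed)
        summaries = {
            f"{group}_graft": median_iqr(graft_d),
            f"{group}_native": median_iqr(native_d),
        }
        return CohortComparison(result, summaries, f"delta:{GRAFT} vs delta:{NATIVE}",
                                comparison, len(in_group) - len(graft_d))

    raise ValueError(f"unknown comparison {comparison!r}")
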