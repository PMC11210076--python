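"""Group comparison statistics.

Per channel pair, two groups of band-averaged scalars are compared with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test; an exact enumeration over
all label assignments is used for small samples (pooled n <= 12), the
tie- and continuity-corrected normal approximation otherwise. Significant
results are optionally confirmed by a Monte Carlo permutation test that
re-randomizes subjects into groups of the original sizes and demands the
observed p-value to be smaller than 95% of the permuted ones.

Multiplicity over a family of N channel pairs is assessed with the exact
binomial tail: the probability of observing X or more nominally significant
outcomes (success probability alpha=0.05 per test) out of N if every null
hypothesis were true.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .bandstats import BandSummaryTable
from .signal_io import ValidationError

EXACT_ENUMERATION_MAX_N = 12


def _midranks_doubled(pooled: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so ties produce exact integers."""
    return np.round(2 * stats.rankdata(pooled)).astype(np.int64)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of label assignments.

    The permutation distribution of the group-a rank sum is symmetric about
    n_a*(N+1)/2 (midrank multiset is symmetric), so the two-sided p is the
    probability of a deviation at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    r2 = _midranks_doubled(pooled)
    n_a, n = len(a), len(pooled)
    obs = int(r2[:n_a].sum())
    center2 = n_a * (n + 1)  # doubled-rank scale
    dev = abs(obs - center2)
    count = total = 0
    for idx in combinations(range(n), n_a):
        s = int(r2[list(idx)].sum())
        total += 1
        if abs(s - center2) >= dev:
            count += 1
    return count / total


def _asymptotic_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normal approximation with tie and continuity corrections."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def wilcoxon_ranksum(a, b) -> tuple[float, str]:
    """Two-sided rank-sum p-value and direction of the median difference.

    Returns (p, direction) with direction "group1_higher" or
    "group2_higher" (ties broken by the mean).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if a.size + b.size <= EXACT_ENUMERATION_MAX_N:
        p = _exact_ranksum_p(a, b)
    else:
        p = _asymptotic_ranksum_p(a, b)
    diff = np.median(a) - np.median(b)
    if diff == 0:
        diff = np.mean(a) - np.mean(b)
    direction = "group1_higher" if diff >= 0 else "group2_higher"
    return min(p, 1.0), direction


def _permuted_ranksum_pvalues(
    a: np.ndarray, b: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized asymptotic rank-sum p-values for random re-assignments.

    The pooled midranks (and hence the tie-corrected null variance) are
    fixed across permutations, so each permutation reduces to summing a
    random subset of ranks.
    """
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = a.size
    ranks = stats.rankdata(pooled)
    # Mann-Whitney U from the group-1 rank sum
    mu_u = n1 * (n - n1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma_u = np.sqrt(n1 * (n - n1) / 12.0 * ((n + 1) - tie_term))
    # random subsets of size n1 via argpartition of random keys
    keys = rng.random((n_permutations, n))
    sel = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
    rank_sums = ranks[sel].sum(axis=1)
    u = rank_sums - n1 * (n1 + 1) / 2.0
    if sigma_u == 0:
        return np.ones(n_permutations)
    z = (np.abs(u - mu_u) - 0.5) / sigma_u  # continuity-corrected
    z = np.maximum(z, 0.0)
    return 2.0 * stats.norm.sf(z)


def permutation_confirmation(
    a, b, n_permutations: int = 16000, seed: int | np.random.Generator | None = None
) -> tuple[bool, float]:
    """Monte Carlo confirmation of a rank-sum result.

    Pooled values are re-randomized into groups of the original sizes
    ``n_permutations`` times and the rank-sum p recomputed each time. The
    observed result is confirmed when its p-value is smaller than 95% of
    the permuted ones. Returns (confirmed, quantile) where quantile is the
    fraction of permuted p-values below the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_permutations < 100:
        raise ValidationError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_obs = _asymptotic_ranksum_p(a, b)
    p_perm = _permuted_ranksum_pvalues(a, b, n_permutations, rng)
    quantile = float(np.mean(p_perm < p_obs))
    return quantile < 0.05, quantile


def binomial_tail(k: int, n: int, p: float = 0.05) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p), evaluated in log space.

    This is the multiple-comparison summary: the chance of k or more
    nominally positive outcomes among n independent tests when every null
    is true.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p < 1:
        raise ValidationError("p must lie in (0, 1)")
    if k == 0:
        return 1.0
    j = np.arange(k, n + 1)
    log_terms = stats.binom.logpmf(j, n, p)
    m = log_terms.max()
    return min(1.0, float(np.exp(m) * np.sum(np.exp(log_terms - m))))


def cohens_d(a, b) -> float:
    """Cohen's d with (n-1)-pooled standard deviation.

    Returns NaN when the pooled variance is zero (undefined effect size).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    if pooled == 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


@dataclass
class GroupComparison:
    pair: str
    p_value: float
    direction: str
    cohens_d: float
    permutation_confirmed: bool | None = None
    permutation_quantile: float | None = None


@dataclass
class MultiplicitySummary:
    n_tests: int
    n_significant: int
    alpha: float
    binomial_tail_probability: float


def compare_groups(
    table1: BandSummaryTable,
    table2: BandSummaryTable,
    n_permutations: int | None = 16000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[list[GroupComparison], MultiplicitySummary]:
    """Per-pair rank-sum comparison of two cohorts plus multiplicity summary.

    Set ``n_permutations`` to None to skip the Monte Carlo confirmation.
    """
    if list(table1.pairs) != list(table2.pairs):
        raise ValueError("summary tables cover different pair universes")
    if table1.band != table2.band or table1.metric != table2.metric:
        raise ValueError("summary tables hold different bands or metrics")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results: list[GroupComparison] = []
    n_sig = 0
    for pair in table1.pairs:
        a = table1.values[pair].dropna().to_numpy()
        b = table2.values[pair].dropna().to_numpy()
        p, direction = wilcoxon_ranksum(a, b)
        d = cohens_d(a, b)
        confirmed = quant = None
        if n_permutations is not None:
            confirmed, quant = permutation_confirmation(a, b, n_permutations, rng)
        if p < alpha:
            n_sig += 1
        results.append(GroupComparison(pair, p, direction, d, confirmed, quant))
    summary = MultiplicitySummary(
        n_tests=len(results),
        n_significant=n_sig,
        alpha=alpha,
        binomial_tail_probability=binomial_tail(n_sig, len(results), alpha),
    )
    return results, summary
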