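import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nvcoh.bandstats import BandSummaryTable, FrequencyBand
from nvcoh.groupstats import (
    binomial_tail,
    cohens_d,
    compare_groups,
    permutation_confirmation,
    wilcoxon_ranksum,
)
from nvcoh.signal_io import ValidationError

MYO = FrequencyBand("myogenic", 0.052, 0.145)


class TestWilcoxonRanksum:
    def test_maximally_separated_small_samples(self):
        # all 20 assignments of {1..6} into groups of 3: the observed split
        # is one of the 2 most extreme -> two-sided p = 2/20
        p, direction = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert direction == "group2_higher"

    def test_identical_samples(self):
        p, _ = wilcoxon_ranksum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_large_shift_detected(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(33) + 10.0
        p, direction = wilcoxon_ranksum(a, b)
        assert p < 1e-3
        assert direction == "group2_higher"

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 4), (5, 5), (6, 6)])
    def test_exact_enumeration_agrees_with_reference(self, na, nb):
        # scipy's exact Mann-Whitney distribution is an independent oracle
        # for tie-free data
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.standard_normal(na)
        b = rng.standard_normal(nb)
        p_ours, _ = wilcoxon_ranksum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p_ours == pytest.approx(ref.pvalue, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.random(20) + 0.2
        b = rng.random(25) + 0.4
        p1, _ = wilcoxon_ranksum(a, b)
        p2, _ = wilcoxon_ranksum(np.log(a), np.log(b))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_type_one_error_calibration(self):
        """Under identical generating distributions the nominal 5% level
        must hold (n = 13 vs 29, the study's presymptomatic split)."""
        rng = np.random.default_rng(42)
        n_sims = 2000
        rejections = 0
        for _ in range(n_sims):
            a = rng.standard_normal(13)
            b = rng.standard_normal(29)
            p, _ = wilcoxon_ranksum(a, b)
            rejections += p < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.015)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_ranksum([1.0], [2.0, 3.0])


class TestBinomialTail:
    def test_certain_event(self):
        assert binomial_tail(0, 55, 0.05) == 1.0

    def test_matches_exact_fraction_arithmetic(self):
        # independent oracle: exact rational-arithmetic tail sum
        from fractions import Fraction
        from math import comb

        p = Fraction(1, 20)
        for k, n in [(3, 10), (14, 120), (36, 55)]:
            exact = sum(
                comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
            )
            assert binomial_tail(k, n, 0.05) == pytest.approx(float(exact), rel=1e-10)

    def test_complement_identity(self):
        k, n, p = 7, 40, 0.05
        head = sum(stats.binom.pmf(j, n, p) for j in range(k))
        assert binomial_tail(k, n, p) + head == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_k_and_p(self):
        assert binomial_tail(5, 55, 0.05) > binomial_tail(6, 55, 0.05)
        assert binomial_tail(5, 55, 0.05) < binomial_tail(5, 55, 0.10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            binomial_tail(56, 55, 0.05)
        with pytest.raises(ValidationError):
            binomial_tail(3, 10, 0.0)


class TestCohensD:
    def test_unit_shift_unit_sd(self, rng):
        b = rng.standard_normal(2000)
        b = (b - b.mean()) / b.std(ddof=1)
        a = b + 1.0
        assert cohens_d(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_zero(self, rng):
        a = rng.standard_normal(30)
        assert cohens_d(a, a) == 0.0

    def test_zero_variance_flagged(self):
        assert np.isnan(cohens_d([1.0, 1.0, 1.0], [1.0, 1.0]))

    def test_estimator_recovers_population_effect(self):
        """Replicated N(1.03,1) vs N(0,1) draws at the study's group sizes
        must centre on the true effect size."""
        rng = np.random.default_rng(7)
        ds = [
            cohens_d(rng.standard_normal(13) + 1.03, rng.standard_normal(29))
            for _ in range(1000)
        ]
        assert np.mean(ds) == pytest.approx(1.03, abs=0.05)


class TestPermutationConfirmation:
    def test_strong_effect_confirmed(self, rng):
        a = rng.standard_normal(13) + 2.0
        b = rng.standard_normal(29)
        confirmed, quantile = permutation_confirmation(a, b, 1000, seed=1)
        assert confirmed
        assert quantile < 0.05

    def test_no_effect_usually_not_confirmed(self, rng):
        confirmed_count = sum(
            permutation_confirmation(
                rng.standard_normal(13), rng.standard_normal(29), 500, seed=k
            )[0]
            for k in range(40)
        )
        assert confirmed_count <= 8  # ~5% expected; generous bound

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValidationError):
            permutation_confirmation(rng.standard_normal(5), rng.standard_normal(5), 50)

    def test_seeded_reproducibility(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(12)
        r1 = permutation_confirmation(a, b, 500, seed=3)
        r2 = permutation_confirmation(a, b, 500, seed=3)
        assert r1 == r2


def make_table(values, pairs, subjects_prefix="s"):
    df = pd.DataFrame(
        values, index=[f"{subjects_prefix}{i}" for i in range(values.shape[0])],
        columns=pairs,
    )
    return BandSummaryTable(MYO, df, "coherence")


class TestCompareGroups:
    def test_identical_tables_nothing_significant(self, rng):
        values = rng.random((8, 4))
        t1 = make_table(values, ["p0", "p1", "p2", "p3"], "a")
        t2 = make_table(values, ["p0", "p1", "p2", "p3"], "b")
        comps, summary = compare_groups(t1, t2, n_permutations=None)
        assert summary.n_significant == 0
        assert summary.binomial_tail_probability == 1.0

    def test_shifted_pairs_detected_with_direction(self, rng):
        pairs = [f"p{j}" for j in range(5)]
        base = rng.standard_normal((20, 5))
        shifted = rng.standard_normal((20, 5)) - 2.0
        t1 = make_table(base, pairs, "a")
        t2 = make_table(shifted, pairs, "b")
        comps, summary = compare_groups(t1, t2, n_permutations=500, seed=0)
        assert summary.n_significant == 5
        assert all(c.direction == "group1_higher" for c in comps)
        assert all(c.cohens_d > 1 for c in comps)
        assert summary.binomial_tail_probability < 1e-6

    def test_pair_universe_mismatch_rejected(self, rng):
        t1 = make_table(rng.random((4, 2)), ["p0", "p1"])
        t2 = make_table(rng.random((4, 2)), ["p0", "p2"])
        with pytest.raises(ValueError, match="pair"):
            compare_groups(t1, t2)
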