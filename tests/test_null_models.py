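"""Null models: sampling, empirical p-values, the exact containment oracle
and multiple-testing adjustment."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbsenrich.alphabet import DNA_BASES
from rbsenrich.kmers import code_to_kmer, incidence_vector, kmer_to_code
from rbsenrich.library import UTRLibrary
from rbsenrich.nulls import (
    NullModelConfig,
    adjust_bonferroni,
    adjust_fdr,
    analytic_pvalue,
    containment_probabilities_all,
    containment_probability,
    containment_probability_any,
    empirical_pvalue,
    expected_occurrences,
    null_exceed_counts,
    permute_library,
    sample_random_library,
)


def brute_force_containment(motif: str, length: int) -> float:
    """Independent oracle: enumerate all 4^length strings."""
    hits = sum(
        motif in "".join(s)
        for s in itertools.product(DNA_BASES, repeat=length)
    )
    return hits / 4**length


class TestSampling:
    def test_degenerate_probabilities(self):
        lib = sample_random_library(1, 4, (1, 0, 0, 0), seed=0)
        assert lib.counts() == {"AAAA": 1}

    def test_mean_cytosine_count_matches_binomial(self):
        lib = sample_random_library(4863, 18, seed=5)
        mean_c = np.mean([s.count("C") for s in lib.expand()])
        assert mean_c == pytest.approx(18 * 0.25, abs=0.1)

    def test_seeded_determinism(self):
        assert sample_random_library(100, 18, seed=9) == sample_random_library(
            100, 18, seed=9
        )

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sample_random_library(5, 4, (0.5, 0.5, 0.5, -0.5))


class TestPermutation:
    def test_homopolymer_fixed_point(self):
        lib = UTRLibrary({"C" * 18: 4})
        assert permute_library(lib, seed=1) == lib

    def test_per_member_composition_preserved(self, naive_500):
        perm = permute_library(naive_500, seed=3)
        orig = sorted("".join(sorted(s)) for s in naive_500.expand())
        after = sorted("".join(sorted(s)) for s in perm.expand())
        assert orig == after

    def test_all_arrangements_equally_likely(self):
        """AACC has 6 distinct arrangements; each should appear ~1/6."""
        lib = UTRLibrary(["AACC"])
        counts: dict[str, int] = {}
        n = 3000
        for seed in range(n):
            (seq,) = list(permute_library(lib, seed=seed))
            counts[seq] = counts.get(seq, 0) + 1
        assert len(counts) == 6
        sigma = math.sqrt(n * (1 / 6) * (5 / 6))
        for c in counts.values():
            assert abs(c - n / 6) < 4 * sigma


class TestEmpiricalPvalue:
    def test_add_one_formula(self):
        assert empirical_pvalue(10, [1, 2, 3]) == pytest.approx(0.25)

    def test_observed_zero_gives_one(self):
        assert empirical_pvalue(0, [0, 1, 5]) == 1.0

    def test_maximum_achieved_once_in_999(self):
        nulls = [0] * 998 + [7]
        assert empirical_pvalue(7, nulls) == pytest.approx(2 / 1000)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1, [])


class TestContainmentOracle:
    def test_cc_in_length_3_uniform(self):
        assert containment_probability("CC", 3) == pytest.approx(7 / 64)
        assert brute_force_containment("CC", 3) == pytest.approx(7 / 64)

    def test_full_length_motif_single_placement(self):
        assert containment_probability("A" * 18, 18) == pytest.approx(0.25**18)

    def test_motif_longer_than_sequence_is_zero(self):
        assert containment_probability("ACGTA", 4) == 0.0

    @pytest.mark.parametrize("motif", ["AAAA", "ACGT", "AGGA", "CCCC", "ATAT"])
    @pytest.mark.parametrize("length", [4, 5, 6, 7])
    def test_matches_brute_force_enumeration(self, motif, length):
        assert containment_probability(motif, length) == pytest.approx(
            brute_force_containment(motif, length), abs=1e-12
        )

    def test_union_oracle_reduces_to_single_motif(self):
        for motif in ["AGGA", "CCC"]:
            assert containment_probability_any([motif], 10) == pytest.approx(
                containment_probability(motif, 10), abs=1e-12
            )

    def test_union_oracle_inclusion_exclusion_two_motifs(self):
        # disjoint-ish motifs: P(A or B) via brute force
        length = 6
        hits = sum(
            ("AGG" in s) or ("CCT" in s)
            for s in ("".join(t) for t in itertools.product(DNA_BASES, repeat=length))
        )
        assert containment_probability_any(["AGG", "CCT"], length) == pytest.approx(
            hits / 4**length, abs=1e-12
        )

    def test_vectorized_all_motifs_matches_scalar(self):
        all_p = containment_probabilities_all(3, 8)
        for code in [0, 17, 33, 63]:
            motif = code_to_kmer(code, 3)
            assert all_p[code] == pytest.approx(
                containment_probability(motif, 8), abs=1e-12
            )

    def test_expected_occurrence_counts_sum_to_window_count(self):
        k, L = 3, 10
        total = sum(
            expected_occurrences(code_to_kmer(c, k), L) for c in range(4**k)
        )
        assert total == pytest.approx(L - k + 1)


class TestAnalyticPvalue:
    def test_observed_zero(self):
        assert analytic_pvalue(0, 10, 0.3) == 1.0

    def test_observed_equals_n(self):
        assert analytic_pvalue(5, 5, 7 / 64) == pytest.approx((7 / 64) ** 5)

    def test_matches_direct_binomial_summation(self):
        n, p, obs = 20, 7 / 64, 5
        direct = sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(obs, n + 1)
        )
        assert analytic_pvalue(obs, n, p) == pytest.approx(direct, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            analytic_pvalue(1, 10, 1.5)
        with pytest.raises(ValueError):
            analytic_pvalue(11, 10, 0.5)


class TestAdjustment:
    def test_bonferroni(self):
        assert adjust_bonferroni(0.002, 100) == pytest.approx(0.2)
        assert adjust_bonferroni(0.5, 10) == 1.0

    def test_bh_hand_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_q_values_dominate_p_values(self, ps):
        q = adjust_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestMonteCarloEngine:
    def test_monte_carlo_agrees_with_analytic(self):
        """Empirical p-value of an observed incidence under the random null
        matches the binomial closed form within 4*sqrt(p(1-p)/N)."""
        motif = "CCACC"
        k, n, N = 5, 300, 1000
        lib = sample_random_library(n, 18, seed=21)
        mat, w = lib.matrix()
        observed_vec = incidence_vector(mat, w, k)
        code = kmer_to_code(motif)
        cfg = NullModelConfig("random_uniform", replicates=N, seed=77)
        exceed = null_exceed_counts(
            lib, k, observed_vec[[code]], cfg, motif_codes=np.array([code])
        )
        p_emp = (1 + exceed[0]) / (N + 1)
        p_true = analytic_pvalue(
            int(observed_vec[code]), n, containment_probability(motif, 18)
        )
        tol = 4 * math.sqrt(p_true * (1 - p_true) / N) + 1 / (N + 1)
        assert abs(p_emp - p_true) <= tol

    def test_permuted_null_of_homopolymer_is_degenerate(self):
        lib = UTRLibrary({"C" * 18: 30})
        mat, w = lib.matrix()
        observed = incidence_vector(mat, w, 4)
        cfg = NullModelConfig("permuted", replicates=50, seed=3)
        exceed = null_exceed_counts(lib, 4, observed, cfg)
        code = kmer_to_code("CCCC")
        # every permuted replicate reproduces the same incidence
        assert exceed[code] == 50
        assert empirical_pvalue(30, [30] * 50) == 1.0
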