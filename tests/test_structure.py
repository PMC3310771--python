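"""Structure scan: molecule assembly, window geometry and the folding model."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbsenrich.alphabet import reverse_complement
from rbsenrich.library import UTRLibrary
from rbsenrich.structure import (
    DEFAULT_DOWNSTREAM26,
    DEFAULT_UPSTREAM26,
    MIN_HAIRPIN,
    STACK_TABLE,
    assemble_molecule,
    dG_profile,
    fold_dG,
    sliding_windows,
)

_PAIRS_WC = {"AT", "TA", "GC", "CG"}
_PAIRS_GU = {"GT", "TG"}


def enumerate_fold(seq: str, allow_gu: bool = True) -> float:
    """Brute-force oracle: minimum energy over all nested pairings."""
    seq = seq.upper().replace("U", "T")

    def pairable(a, b):
        p = a + b
        return p in _PAIRS_WC or (allow_gu and p in _PAIRS_GU)

    def structures(i, j):
        if j - i < MIN_HAIRPIN + 1:
            yield []
            return
        yield from structures(i + 1, j)
        for t in range(i + MIN_HAIRPIN + 1, j + 1):
            if pairable(seq[i], seq[t]):
                for left in structures(i + 1, t - 1):
                    for right in structures(t + 1, j):
                        yield [(i, t)] + left + right

    def energy(pairs):
        pset = set(pairs)
        total = 0.0
        for (i, j) in pairs:
            if (i + 1, j - 1) in pset:
                total += STACK_TABLE[(seq[i] + seq[j], seq[i + 1] + seq[j - 1])]
        return total

    return min((energy(p) for p in structures(0, len(seq) - 1)), default=0.0)


class TestAssembly:
    def test_block_construction(self):
        mol = assemble_molecule("C" * 18, "A" * 26, "G" * 26)
        assert len(mol.bases) == 70
        assert mol.bases[26:44] == "C" * 18

    def test_default_flanks_embed_fixed_context(self):
        mol = assemble_molecule("TAAGAAGGAGATATATCC")
        assert mol.bases[16:26] == "TGTTTAACTT"
        assert mol.bases[44:54] == "ATGGCGGACT"

    def test_wrong_piece_lengths_rejected(self):
        with pytest.raises(ValueError):
            assemble_molecule("C" * 17)
        with pytest.raises(ValueError):
            assemble_molecule("C" * 18, "A" * 25, "G" * 26)


class TestWindows:
    def test_default_geometry_five_windows(self):
        mol = assemble_molecule("C" * 18)
        windows = sliding_windows(mol)
        assert [s for s, _ in windows] == [0, 10, 20, 30, 40]
        assert all(len(w) == 30 for _, w in windows)

    def test_minimal_molecule_single_window(self):
        assert len(sliding_windows("A" * 30)) == 1

    def test_consecutive_windows_share_twenty_bases(self):
        mol = assemble_molecule("C" * 18)
        windows = sliding_windows(mol)
        for (s1, w1), (s2, w2) in zip(windows, windows[1:]):
            assert w1[10:] == w2[:20]

    def test_non_tiling_geometry_rejected(self):
        with pytest.raises(ValueError):
            sliding_windows("A" * 65, 30, 10)


class TestFold:
    def test_homopolymers_score_zero(self):
        for base in "ACGT":
            assert fold_dG(base * 30) == 0.0

    def test_short_windows_score_zero(self):
        for seq in ["GC", "GGGCCC"[:6], "AUGCAU"]:
            assert fold_dG(seq) == 0.0

    def test_stem_more_negative_than_homopolymer(self):
        hairpin = "GGGGG" + "AAAA" + "CCCCC" + "A" * 16
        assert fold_dG(hairpin) < 0.0
        assert fold_dG(hairpin) < fold_dG("A" * 30)

    def test_longer_stem_never_raises_energy(self):
        e_prev = 0.0
        for stem in range(2, 7):
            seq = "G" * stem + "AAAA" + "C" * stem
            e = fold_dG(seq)
            assert e <= e_prev + 1e-12
            e_prev = e

    def test_u_t_rendering_invariant(self):
        seq = "GGGGGAAAACCCCC"
        assert fold_dG(seq) == fold_dG(seq.replace("T", "U").replace("G", "G"))
        assert fold_dG("GCAUGCAUGCAU") == fold_dG("GCATGCATGCAT")

    def test_strand_symmetry_without_wobble(self, rng):
        """fold(x) == fold(revcomp(x)) when only Watson-Crick pairs exist."""
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            rc = reverse_complement(seq)
            assert fold_dG(seq, allow_gu=False) == pytest.approx(
                fold_dG(rc, allow_gu=False), abs=1e-9
            )

    def test_strand_symmetry_gc_only_with_wobble(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("GC"), size=12))
            rc = reverse_complement(seq)
            assert fold_dG(seq) == pytest.approx(fold_dG(rc), abs=1e-9)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, seq):
        assert fold_dG(seq) == pytest.approx(enumerate_fold(seq), abs=1e-9)

    def test_external_folder_hook(self):
        assert fold_dG("GGGGAAAACCCC", folder=lambda s: -7.25) == -7.25


class TestProfile:
    def test_planted_hairpin_lowers_containing_window(self):
        # 7-bp palindromic stem with a 4-base loop, fully inside window 3
        hairpin_region = "GCGCGCG" + "AAAA" + "CGCGCGC"
        lib = UTRLibrary({hairpin_region: 60})
        profile = dG_profile(lib, simulated_n=60, seed=1)
        summ = profile["summary"].set_index(["set", "ordinal"])
        assert (
            summ.loc[("library", 3), "median_dG"]
            < summ.loc[("simulated", 3), "median_dG"] - 3.0
        )

    def test_uniform_library_matches_simulated_distribution(self, naive_500):
        sub = UTRLibrary(dict(list(naive_500.counts().items())[:150]))
        profile = dG_profile(sub, simulated_n=150, seed=2)
        summ = profile["summary"].set_index(["set", "ordinal"])
        for ordinal in range(1, 6):
            diff = abs(
                summ.loc[("library", ordinal), "median_dG"]
                - summ.loc[("simulated", ordinal), "median_dG"]
            )
            assert diff < 3.0  # kcal/mol, Monte-Carlo slack at n=150

    def test_deterministic_under_seed(self):
        lib = UTRLibrary(["GCGCGCGCGCGCGCGCGC"])
        a = dG_profile(lib, simulated_n=20, seed=5)
        b = dG_profile(lib, simulated_n=20, seed=5)
        assert a["summary"].equals(b["summary"])
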