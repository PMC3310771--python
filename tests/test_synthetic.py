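"""Synthetic library generator: composition calibration and determinism."""
import numpy as np
import pytest
from scipy import stats

from rbsenrich.library import UTRLibrary
from rbsenrich.nulls import containment_probability_any
from rbsenrich.reads import ReadTemplate, filter_reads
from rbsenrich.sd import (
    SDMotifSet,
    base_composition_by_position,
    cytosine_histogram,
    partition_library,
)
from rbsenrich.synthetic import (
    SD_CORE_MOTIFS,
    GeneratorConfig,
    c_probability_for_tail,
    generate_naive_library,
    generate_selected_library,
    parse_ground_truth,
    theoretical_diversity,
    sci_notation,
    wrap_reads,
)


class TestNaiveLibrary:
    def test_degenerate_distribution_gives_homopolymer(self):
        cfg = GeneratorConfig(library_size=1, base_probs=(0, 1, 0, 0))
        lib = generate_naive_library(cfg)
        assert lib.counts() == {"C" * 18: 1}

    def test_per_position_frequencies_near_uniform(self, naive_4863):
        comp = base_composition_by_position(naive_4863)
        assert comp.shape == (4, 18)
        # 3-sigma binomial tolerance at n=4863 is ~0.019
        assert np.all(np.abs(comp.values - 0.25) < 0.02)

    def test_seeded_determinism(self):
        cfg = GeneratorConfig(library_size=1000, seed=7)
        assert generate_naive_library(cfg) == generate_naive_library(cfg)

    def test_different_seeds_differ(self):
        a = generate_naive_library(GeneratorConfig(library_size=200, seed=1))
        b = generate_naive_library(GeneratorConfig(library_size=200, seed=2))
        assert a != b

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(library_size=10, base_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            GeneratorConfig(library_size=0)


class TestSelectedLibrary:
    def test_forced_planting_at_point_mass_offset(self):
        dist = [0.0] * 18
        dist[6] = 1.0
        cfg = GeneratorConfig(
            library_size=50,
            sd_fraction=1.0,
            sd_motif_weights={"GGAG": 1.0},
            sd_position_distribution=tuple(dist),
            seed=3,
        )
        lib = generate_selected_library(cfg)
        assert all(seq[6:10] == "GGAG" for seq in lib)

    def test_round3_composition_targets(self):
        """Observed SD fraction ~0.24 and >=9-C fraction of non-SD ~0.61."""
        cfg = GeneratorConfig(library_size=4863, sd_fraction=0.24, seed=11)
        lib = generate_selected_library(cfg)
        sd_lib, non_sd = partition_library(lib, SDMotifSet.core())
        assert sd_lib.total / lib.total == pytest.approx(0.24, abs=0.02)
        hist = cytosine_histogram(non_sd)
        assert hist.fraction_at_least(9) == pytest.approx(0.61, abs=0.03)

    def test_chance_sd_level_matches_containment_oracle(self):
        """With no planting, SD classification happens at the exact analytic
        containment probability of the five-motif union."""
        cfg = GeneratorConfig(
            library_size=5000, sd_fraction=0.0, crich_c_prob=0.25, seed=23
        )
        lib = generate_selected_library(cfg)
        sd_lib, _ = partition_library(lib)
        p = containment_probability_any(SD_CORE_MOTIFS, 18, (0.25,) * 4)
        sigma = np.sqrt(p * (1 - p) / 5000)
        assert abs(sd_lib.total / lib.total - p) < 3 * sigma

    def test_calibrated_c_probability_hits_tail_target(self):
        """The binomial-tail solve puts P(>=9 C) at 0.61 exactly; the
        generator reproduces it empirically (sd_fraction=0)."""
        p = c_probability_for_tail(0.61, 9, 18)
        assert stats.binom.sf(8, 18, p) == pytest.approx(0.61, abs=1e-9)
        cfg = GeneratorConfig(library_size=5000, sd_fraction=0.0, seed=29)
        lib = generate_selected_library(cfg)
        frac = cytosine_histogram(lib).fraction_at_least(9)
        assert frac == pytest.approx(0.61, abs=0.03)

    def test_planted_motif_longer_than_region_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(library_size=10, planted_motifs=(("A" * 19, 0.1),))

    def test_planted_motif_fraction_applied(self):
        cfg = GeneratorConfig(
            library_size=1000, sd_fraction=0.0, planted_motifs=(("CCACC", 0.5),),
            crich_c_prob=0.25, seed=5,
        )
        lib = generate_selected_library(cfg)
        carriers = sum(m for s, m in lib.counts().items() if "CCACC" in s)
        assert carriers >= 500  # planted half, plus chance carriers


class TestWrapReads:
    def test_error_free_round_trip(self, naive_500):
        reads = wrap_reads(naive_500, ReadTemplate())
        recovered, report = filter_reads(reads)
        # naive members with an in-frame ATG are filtered by design
        expected = UTRLibrary(
            {s: c for s, c in naive_500.counts().items()
             if not any(s[o:o + 3] == "ATG" for o in range(0, 16, 3))}
        )
        assert recovered == expected
        assert report.rejected_no_locus == report.rejected_flank == 0
        assert report.rejected_length == 0

    def test_all_indel_reads_rejected(self):
        lib = UTRLibrary(["CCCCCCCCCCCCCCCCCC", "ACACACACACACACACAC"])
        cfg = GeneratorConfig(library_size=2, length_error_rate=1.0, seed=8)
        reads = wrap_reads(lib, ReadTemplate(), cfg)
        recovered, report = filter_reads(reads)
        assert report.accepted == 0
        assert report.rejected_length == report.total_reads

    def test_rejections_match_ground_truth_bookkeeping(self):
        """With substitution errors only, flank rejections equal the count of
        reads whose mutations hit the 10-base flanks (per the identifiers)."""
        lib = UTRLibrary({"CCCCCCCCCCCCCCCCCC": 2000})
        cfg = GeneratorConfig(library_size=2000, error_rate=0.01, seed=13)
        reads = wrap_reads(lib, ReadTemplate(), cfg)
        truth = [parse_ground_truth(r.id) for r in reads]
        flank_hit = sum(1 for t in truth if t["nsub_flank"] > 0)
        _, report = filter_reads(reads)
        assert report.rejected_no_locus + report.rejected_flank == flank_hit
        # remaining rejections must be in-frame ATGs created inside the region
        assert (
            report.accepted + report.rejected_inframe_start
            == report.total_reads - flank_hit
        )

    def test_wrap_is_deterministic(self, naive_500):
        cfg = GeneratorConfig(library_size=500, error_rate=0.02, seed=4)
        a = wrap_reads(naive_500, ReadTemplate(), cfg)
        b = wrap_reads(naive_500, ReadTemplate(), cfg)
        assert [(r.id, r.bases) for r in a] == [(r.id, r.bases) for r in b]


def test_theoretical_diversity_rendering():
    assert theoretical_diversity(18) == 4**18
    assert sci_notation(theoretical_diversity(18)) == "6.9e+10"
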