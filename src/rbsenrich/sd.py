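"""Shine-Dalgarno classification and composition statistics.

A region is an SD candidate iff it contains at least one of the four-base
motifs AAGG, AGGA, GGAG, GAGG, AGGT (AGGU in RNA) — the windows of the
anti-SD that admit canonical pairing.  An extended set — all ten four-base
windows of the reverse complement of the 13-base unpaired 3' tail of the
16S rRNA (5'-GAUCACCUCCUUA-3') — is available for positional profiling.

Positions are rendered -18..-1 relative to the start codon (-1 adjacent to
the AUG).  Positional profiles count occurrences per offset, so one member
may contribute to several offsets; overall classification counts members.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import normalize, reverse_complement, to_dna
from .library import UTRLibrary
from .synthetic import SD_CORE_MOTIFS

#: Unpaired 3' tail of the E. coli 16S rRNA (anti-SD context), 5'->3'.
SIXTEEN_S_TAIL_RNA = "GAUCACCUCCUUA"


def extended_sd_motifs(tail: str = SIXTEEN_S_TAIL_RNA, k: int = 4) -> tuple[str, ...]:
    """All k-base windows of the reverse complement of the 16S 3' tail (DNA)."""
    rc = to_dna(reverse_complement(tail))
    return tuple(rc[i : i + k] for i in range(len(rc) - k + 1))


@dataclass(frozen=True)
class SDMotifSet:
    """Ordered motif list used for SD candidacy and profiling."""

    motifs: tuple[str, ...] = SD_CORE_MOTIFS

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("motif set must be non-empty")
        object.__setattr__(self, "motifs", tuple(normalize(m) for m in self.motifs))

    @classmethod
    def core(cls) -> "SDMotifSet":
        return cls(SD_CORE_MOTIFS)

    @classmethod
    def extended(cls) -> "SDMotifSet":
        return cls(extended_sd_motifs())


@dataclass
class PositionalProfile:
    """Occurrence counts of one motif by region start offset."""

    motif: str
    counts: np.ndarray
    library_size: int
    region_length: int

    @property
    def positions(self) -> list[int]:
        """Start offsets rendered relative to the start codon (-L..-1)."""
        return [o - self.region_length for o in range(len(self.counts))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "offset": np.arange(len(self.counts)),
                "count": self.counts,
                "frequency": self.counts / max(1, self.library_size),
            }
        )


def classify_sd(
    region: str, motif_set: SDMotifSet | None = None
) -> tuple[bool, list[str]]:
    """(is_sd, matched motifs): substring containment against the motif set."""
    if motif_set is None:
        motif_set = SDMotifSet.core()
    seq = normalize(region)
    matched = [m for m in motif_set.motifs if m in seq]
    return bool(matched), matched


def partition_library(
    library: UTRLibrary, motif_set: SDMotifSet | None = None
) -> tuple[UTRLibrary, UTRLibrary]:
    """Split into (SD, non-SD) libraries, preserving multiplicities."""
    if motif_set is None:
        motif_set = SDMotifSet.core()
    sd, non_sd = UTRLibrary(), UTRLibrary()
    for seq, count in library.counts().items():
        target = sd if classify_sd(seq, motif_set)[0] else non_sd
        target.add(seq, count)
    return sd, non_sd


def positional_motif_frequency(library: UTRLibrary, motif: str) -> PositionalProfile:
    """Occurrence counts of the motif at each region start offset."""
    motif = normalize(motif)
    if library.total == 0:
        raise ValueError("empty library")
    L = library.region_length
    if len(motif) >= L + 1:
        raise ValueError("motif longer than region")
    n_offsets = L - len(motif) + 1
    counts = np.zeros(n_offsets, dtype=np.int64)
    for seq, mult in library.counts().items():
        for o in range(n_offsets):
            if seq[o : o + len(motif)] == motif:
                counts[o] += mult
    return PositionalProfile(
        motif=motif, counts=counts, library_size=library.total, region_length=L
    )


def base_composition_by_position(library: UTRLibrary) -> pd.DataFrame:
    """4 x L frequency matrix (rows A,C,G,T; columns -L..-1), weight = reads."""
    if library.total == 0:
        raise ValueError("empty library")
    mat, weights = library.matrix()
    L = mat.shape[1]
    freq = np.zeros((4, L))
    for b in range(4):
        freq[b] = ((mat == b) * weights[:, None]).sum(axis=0)
    freq /= weights.sum()
    return pd.DataFrame(freq, index=list("ACGT"), columns=[p - L for p in range(L)])


@dataclass
class CytosineHistogram:
    """Histogram of per-member cytosine counts (multiplicity-weighted)."""

    counts: np.ndarray  # indexed 0..max length
    total: int

    def fraction_at_least(self, threshold: int) -> float:
        if self.total == 0:
            return 0.0
        return float(self.counts[threshold:].sum() / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"c_count": np.arange(len(self.counts)), "members": self.counts}
        )


def cytosine_count(seq: str) -> int:
    return normalize(seq).count("C")


def cytosine_histogram(library) -> CytosineHistogram:
    """Accepts a UTRLibrary or any iterable of sequences (arbitrary lengths),
    e.g. natural 5' UTR sets read from FASTA."""
    if isinstance(library, UTRLibrary):
        items = library.counts().items()
    else:
        items = [(normalize(s), 1) for s in library]
    max_len = max((len(s) for s, _ in items), default=0)
    counts = np.zeros(max_len + 1, dtype=np.int64)
    total = 0
    for seq, mult in items:
        counts[seq.count("C")] += mult
        total += mult
    return CytosineHistogram(counts=counts, total=total)


def classification_table(
    library: UTRLibrary, motif_set: SDMotifSet | None = None
) -> pd.DataFrame:
    """Per-member classification (one row per unique sequence)."""
    rows = []
    for seq, count in library.counts().items():
        is_sd, matched = classify_sd(seq, motif_set)
        rows.append(
            {
                "region": seq,
                "multiplicity": count,
                "is_sd": is_sd,
                "matched_motifs": ",".join(matched),
                "c_count": seq.count("C"),
            }
        )
    return pd.DataFrame(rows)
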