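"""mRNA-rRNA complementarity scan.

Every length-k window of an rRNA sequence (k = 4..8) is tested for
overrepresentation of its strict Watson-Crick reverse complement among the
library regions.  Each window receives two empirical p-values — P.rand from
random virtual libraries and P.perm from per-read permuted libraries — which
are Bonferroni-corrected within the per-k window family (m = |rRNA| - k + 1)
and thresholded at 0.01.  For k = 7, significant windows that share six
bases with a significant neighbour are merged into groups; the grouped
intervals are the hand-off to any structure-viewer rendering.

rRNA window indices are 1-based at the window's first base.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import is_rna_rendering, normalize, reverse_complement, to_dna, to_rna
from .kmers import incidence_vector, kmer_to_code
from .library import UTRLibrary, _open_text
from .nulls import NullModelConfig, null_exceed_counts


@dataclass(frozen=True)
class RRNASequence:
    """An rRNA sequence; T is accepted and normalized, rendering remembered."""

    name: str
    bases: str

    def __post_init__(self):
        object.__setattr__(self, "_rna", is_rna_rendering(self.bases))
        object.__setattr__(self, "bases", normalize(self.bases))
        if not self.bases:
            raise ValueError("rRNA sequence is empty")

    def render(self, seq: str) -> str:
        return to_rna(seq) if self._rna else seq

    def __len__(self) -> int:
        return len(self.bases)

    @classmethod
    def from_fasta(cls, path: str | Path) -> list["RRNASequence"]:
        with _open_text(path) as handle:
            return [
                cls(name=rec.id, bases=str(rec.seq))
                for rec in SeqIO.parse(handle, "fasta")
            ]


def enumerate_windows(rrna: RRNASequence | str, k: int) -> list[tuple[int, str]]:
    """All (1-based index, window) pairs of length k along the sequence."""
    if isinstance(rrna, RRNASequence):
        seq, render = rrna.bases, rrna.render
    else:
        rna = is_rna_rendering(rrna)
        seq = normalize(rrna)
        render = to_rna if rna else (lambda s: s)
    if not 1 <= k <= len(seq):
        raise ValueError(f"k={k} outside [1, {len(seq)}]")
    return [(i + 1, render(seq[i : i + k])) for i in range(len(seq) - k + 1)]


def incidence_of_complement(library: UTRLibrary, window: str) -> int:
    """Members (multiplicity-weighted) containing the window's reverse complement."""
    if library.total == 0:
        return 0
    target = to_dna(reverse_complement(window))
    if len(target) > library.region_length:
        return 0
    return sum(
        mult for seq, mult in library.counts().items() if target in seq
    )


@dataclass
class WindowGroup:
    """A run of >= 2 consecutive significant k-windows, merged to one interval."""

    rrna_name: str
    k: int
    first_index: int
    last_index: int

    @property
    def span(self) -> tuple[int, int]:
        """Merged rRNA interval, 1-based inclusive."""
        return (self.first_index, self.last_index + self.k - 1)

    @property
    def member_indices(self) -> list[int]:
        return list(range(self.first_index, self.last_index + 1))


def rrna_scan(
    library: UTRLibrary,
    rrna: RRNASequence,
    ks: Sequence[int] = (4, 5, 6, 7, 8),
    *,
    replicates: int = 1000,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    alpha: float = 0.01,
    occurrences: bool = False,
) -> pd.DataFrame:
    """Scan the rRNA against the library under both nulls.

    Null replicate libraries are shared across all windows of the same k
    (one replicate yields the full incidence vector).  The Bonferroni
    multiplier is the per-k window count on this rRNA.

    Returns a tidy frame with one row per (k, index):
    rrna_name, k, index, window, complement, incidence, p_rand, p_perm,
    p_rand_adj, p_perm_adj, significant.
    """
    if library.total == 0:
        raise ValueError("library must be non-empty")
    ss = np.random.SeedSequence(seed)
    rng_rand, rng_perm = (np.random.default_rng(c) for c in ss.spawn(2))
    frames = []
    mat, weights = library.matrix()
    for k in ks:
        if not 1 <= k <= library.region_length:
            raise ValueError(f"k={k} outside [1, region length]")
        windows = enumerate_windows(rrna, k)
        m = len(windows)
        codes = np.array(
            [kmer_to_code(to_dna(reverse_complement(w))) for _, w in windows]
        )
        observed_full = incidence_vector(mat, weights, k, occurrences=occurrences)
        observed = observed_full[codes]
        cfg_rand = NullModelConfig("random_uniform", replicates, tuple(base_probs))
        cfg_perm = NullModelConfig("permuted", replicates)
        exceed_rand = null_exceed_counts(
            library, k, observed, cfg_rand, motif_codes=codes, rng=rng_rand,
            occurrences=occurrences,
        )
        exceed_perm = null_exceed_counts(
            library, k, observed, cfg_perm, motif_codes=codes, rng=rng_perm,
            occurrences=occurrences,
        )
        p_rand = (1 + exceed_rand) / (replicates + 1)
        p_perm = (1 + exceed_perm) / (replicates + 1)
        frame = pd.DataFrame(
            {
                "rrna_name": rrna.name,
                "k": k,
                "index": [idx for idx, _ in windows],
                "window": [w for _, w in windows],
                "complement": [reverse_complement(w) for _, w in windows],
                "incidence": observed,
                "p_rand": p_rand,
                "p_perm": p_perm,
            }
        )
        frame["p_rand_adj"] = np.minimum(1.0, frame["p_rand"] * m)
        frame["p_perm_adj"] = np.minimum(1.0, frame["p_perm"] * m)
        frame["significant"] = frame["p_rand_adj"] < alpha
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def group_significant_windows(
    records: pd.DataFrame, k: int = 7
) -> list[WindowGroup]:
    """Maximal runs (length >= 2) of consecutive significant k-window indices."""
    sub = records[(records["k"] == k) & records["significant"]]
    if sub.empty:
        return []
    names = sub["rrna_name"].unique()
    if len(names) > 1:
        raise ValueError("records must all come from one rRNA")
    indices = sorted(sub["index"].tolist())
    groups: list[WindowGroup] = []
    run_start = prev = indices[0]
    for idx in indices[1:] + [None]:
        if idx is not None and idx == prev + 1:
            prev = idx
            continue
        if prev > run_start:  # run length >= 2
            groups.append(
                WindowGroup(
                    rrna_name=str(names[0]), k=k,
                    first_index=run_start, last_index=prev,
                )
            )
        if idx is not None:
            run_start = prev = idx
    return groups


def groups_to_bed(groups: Iterable[WindowGroup], path: str | Path) -> None:
    """Write merged spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, g in enumerate(groups, start=1):
            start, end = g.span
            fh.write(f"{g.rrna_name}\t{start - 1}\t{end}\tgroup_{i}\n")
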