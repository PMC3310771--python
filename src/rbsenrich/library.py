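"""The UTRLibrary container: a multiset of fixed-length 5' UTR regions.

The unit of every statistic in this package is the randomized region (by
default 18 bases immediately upstream of the start codon).  A library is a
multiset of such regions — reads carrying identical regions are collapsed to
one member with a multiplicity — and all downstream counts are
multiplicity-weighted unless the caller collapses to unique sequences.
"""
from __future__ import annotations

import gzip
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import encode_many, normalize, to_rna


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class UTRLibrary:
    """Multiset of equal-length nucleotide regions with read multiplicities."""

    def __init__(self, members: Iterable[str] | Mapping[str, int] = ()):
        self._counts: dict[str, int] = {}
        if isinstance(members, Mapping):
            for seq, count in members.items():
                self.add(seq, count)
        else:
            for seq in members:
                self.add(seq)

    def add(self, seq: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("multiplicity must be >= 1")
        s = normalize(seq)
        cur = self._counts.get(s)
        if cur is None:
            if self._counts:
                L = len(next(iter(self._counts)))
                if len(s) != L:
                    raise ValueError(
                        f"region length {len(s)} != library region length {L}"
                    )
            self._counts[s] = count
        else:
            self._counts[s] = cur + count

    # -- basic queries -------------------------------------------------
    @property
    def total(self) -> int:
        """Number of reads (multiplicity-weighted size)."""
        return sum(self._counts.values())

    @property
    def n_unique(self) -> int:
        return len(self._counts)

    @property
    def region_length(self) -> int:
        if not self._counts:
            raise ValueError("empty library has no region length")
        return len(next(iter(self._counts)))

    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def multiplicity(self, seq: str) -> int:
        return self._counts.get(normalize(seq), 0)

    def __len__(self) -> int:
        return self.total

    def __iter__(self):
        return iter(self._counts)

    def __contains__(self, seq: str) -> bool:
        return normalize(seq) in self._counts

    def __eq__(self, other) -> bool:
        if not isinstance(other, UTRLibrary):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        return f"UTRLibrary(total={self.total}, unique={self.n_unique})"

    def expand(self):
        """Yield every read's region, repeating by multiplicity."""
        for seq, count in self._counts.items():
            for _ in range(count):
                yield seq

    def collapse_unique(self) -> "UTRLibrary":
        """Library with every multiplicity set to 1 (unique-sequence mode)."""
        return UTRLibrary({seq: 1 for seq in self._counts})

    # -- numeric views -------------------------------------------------
    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique-member uint8 matrix, multiplicity weight vector).

        Rows are sorted lexicographically so that every matrix-based
        computation — including the permutation null, which consumes
        randomness per row — is invariant to member insertion order.
        """
        seqs = sorted(self._counts)
        weights = np.array([self._counts[s] for s in seqs], dtype=np.int64)
        return encode_many(seqs), weights

    def expanded_matrix(self) -> np.ndarray:
        """(total, L) uint8 matrix with one row per read."""
        mat, weights = self.matrix()
        return np.repeat(mat, weights, axis=0)

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "UTRLibrary":
        return cls(seqs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "UTRLibrary":
        """Read a library from FASTA; `count=N` in a description restores
        multiplicities written by :meth:`to_fasta`."""
        lib = cls()
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                count = 1
                for token in rec.description.split():
                    if token.startswith("count="):
                        count = int(token.split("=", 1)[1])
                lib.add(str(rec.seq), count)
        return lib

    @classmethod
    def from_text(cls, path: str | Path) -> "UTRLibrary":
        """One sequence per line."""
        with _open_text(path) as handle:
            return cls(line.strip() for line in handle if line.strip())

    def to_fasta(self, path: str | Path, *, rna: bool = False) -> None:
        records = []
        for i, (seq, count) in enumerate(self._counts.items(), start=1):
            s = to_rna(seq) if rna else seq
            records.append(
                SeqRecord(Seq(s), id=f"region_{i}", description=f"count={count}")
            )
        with _open_text(path, "wt") as handle:
            SeqIO.write(records, handle, "fasta")

    def to_text(self, path: str | Path, *, rna: bool = False) -> None:
        with _open_text(path, "wt") as handle:
            for seq in self.expand():
                handle.write((to_rna(seq) if rna else seq) + "\n")
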