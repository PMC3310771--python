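"""Nucleotide alphabet utilities.

Everything inside the package is DNA ({A,C,G,T}); RNA input (U) is mapped to
T on ingestion, and outputs can be rendered back as RNA where that is the
conventional presentation (e.g. rRNA windows).
"""
from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}

_RNA_TO_DNA = str.maketrans("uU", "tT")
_DNA_TO_RNA = str.maketrans("tT", "uU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A sequence contains characters outside the accepted nucleotide set."""


def normalize(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase a sequence and map U to T, validating the alphabet.

    Parameters
    ----------
    seq
        Nucleotide string, DNA or RNA, any case.
    allow_n
        Permit the ambiguity code N (used for raw sequencing reads only).
    """
    s = seq.upper().translate(_RNA_TO_DNA)
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def is_rna_rendering(seq: str) -> bool:
    """Heuristic used to echo a sequence back in the alphabet it arrived in."""
    u = seq.upper()
    return "U" in u and "T" not in u


def to_rna(seq: str) -> str:
    return seq.upper().translate(_DNA_TO_RNA)


def to_dna(seq: str) -> str:
    return seq.upper().translate(_RNA_TO_DNA)


def reverse_complement(seq: str, rna: bool | None = None) -> str:
    """Strict Watson-Crick reverse complement (A:T/U, C:G; no wobble).

    The output alphabet (RNA vs DNA rendering) matches the input; sequences
    containing neither U nor T are rendered as DNA unless ``rna=True``.
    """
    if rna is None:
        rna = is_rna_rendering(seq)
    s = normalize(seq)
    rc = s.translate(_COMPLEMENT)[::-1]
    return to_rna(rc) if rna else rc


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 vector with A=0, C=1, G=2, T=3."""
    s = normalize(seq)
    return np.array([BASE_INDEX[c] for c in s], dtype=np.uint8)


_DECODE = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length DNA strings as an (n, L) uint8 matrix."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be of equal length")
    raw = np.frombuffer("".join(normalize(s) for s in seqs).encode("ascii"), dtype=np.uint8)
    mat = raw.reshape(len(seqs), L)
    out = np.zeros_like(mat)
    for base, idx in BASE_INDEX.items():
        out[mat == ord(base)] = idx
    return out


def decode_row(row: np.ndarray) -> str:
    return _DECODE[np.asarray(row, dtype=np.intp)].tobytes().decode("ascii")
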