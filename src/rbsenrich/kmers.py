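"""Shared k-mer machinery: integer window codes and incidence vectors.

A k-mer over {A,C,G,T} is identified with its base-4 integer code
(A=0, C=1, G=2, T=3, most significant base first).  All motif counting in
the package — the exhaustive motif search, the rRNA complementarity scan and
the Monte-Carlo null replicates — reduces to building incidence vectors over
the 4^k code space, so this module is deliberately small and fast.
"""
from __future__ import annotations

import numpy as np

from .alphabet import BASE_INDEX, DNA_BASES, normalize


def kmer_to_code(kmer: str) -> int:
    code = 0
    for c in normalize(kmer):
        code = code * 4 + BASE_INDEX[c]
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(DNA_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def window_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of all length-k windows of each row.

    Parameters
    ----------
    mat
        (n, L) uint8 matrix of encoded sequences.
    k
        Window length, 1 <= k <= L.

    Returns
    -------
    (n, L-k+1) int64 array of window codes.
    """
    n, L = mat.shape
    if not 1 <= k <= L:
        raise ValueError(f"k={k} outside [1, {L}]")
    W = L - k + 1
    codes = np.zeros((n, W), dtype=np.int64)
    for j in range(k):
        codes += mat[:, j : j + W].astype(np.int64) << (2 * (k - 1 - j))
    return codes


def incidence_vector(
    mat: np.ndarray,
    weights: np.ndarray | None,
    k: int,
    *,
    occurrences: bool = False,
) -> np.ndarray:
    """Per-motif incidence over all 4^k motifs.

    By default "incidence" counts sequences containing the motif at least
    once (presence/absence per row, weighted by ``weights`` — read
    multiplicities).  With ``occurrences=True`` every window occurrence is
    counted instead.
    """
    n = mat.shape[0]
    size = 4**k
    if n == 0:
        return np.zeros(size, dtype=np.int64)
    codes = window_codes(mat, k)
    if weights is None:
        weights = np.ones(n, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.int64)
    if occurrences:
        w = np.repeat(weights, codes.shape[1])
        return np.bincount(codes.ravel(), weights=w, minlength=size).astype(np.int64)
    codes = np.sort(codes, axis=1)
    first = np.ones_like(codes, dtype=bool)
    first[:, 1:] = codes[:, 1:] != codes[:, :-1]
    rows = np.broadcast_to(np.arange(n)[:, None], codes.shape)
    return np.bincount(
        codes[first], weights=weights[rows[first]].astype(np.float64), minlength=size
    ).astype(np.int64)


def distinct_kmer_sets(mat: np.ndarray, k: int) -> list[set[int]]:
    """Per-row sets of distinct k-mer codes (used by slow oracles in tests)."""
    codes = window_codes(mat, k)
    return [set(row.tolist()) for row in codes]
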