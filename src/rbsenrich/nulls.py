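"""Null models and shared statistics for motif enrichment.

Two empirical nulls are provided, mirroring the two p-value families of the
analysis:

* ``random_uniform`` — virtual libraries of i.i.d. random regions, equal in
  size to the observed pool (sensitive to base composition and base order);
* ``permuted`` — the observed library with every read's region independently
  shuffled (composition preserved per read; sensitive to base order only).

Empirical p-values use the add-one (pseudo-count) Monte-Carlo estimator, so
they are never exactly zero and remain stable under Bonferroni correction.
An exact automaton-based containment-probability oracle and its binomial
closed form stand in for infinite replicates; they double as the independent
cross-check for the Monte-Carlo machinery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .alphabet import decode_row, normalize
from .kmers import incidence_vector
from .library import UTRLibrary

UNIFORM_PROBS = (0.25, 0.25, 0.25, 0.25)


def _validate_probs(base_probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("base_probs must be 4 probabilities in [0,1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must sum to 1")
    return p


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration of one empirical null.

    ``replicates`` defaults to a desk-scale 1,000; the original analysis used
    ~100,000 virtual libraries, reachable via the CLI ``--replicates`` flag.
    """

    kind: Literal["random_uniform", "permuted"] = "random_uniform"
    replicates: int = 1000
    base_probs: tuple[float, float, float, float] = UNIFORM_PROBS
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        _validate_probs(self.base_probs)


@dataclass
class NullDistribution:
    """Null counts of one statistic plus the observed value."""

    statistic_name: str
    null_counts: np.ndarray
    observed: int

    @property
    def pvalue(self) -> float:
        return empirical_pvalue(self.observed, self.null_counts)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def random_region_matrix(
    n: int, length: int, base_probs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """(n, length) uint8 matrix of i.i.d. draws from base_probs."""
    p = _validate_probs(base_probs)
    cum = np.cumsum(p)
    u = rng.random((n, length))
    return np.searchsorted(cum, u, side="right").astype(np.uint8)


def sample_random_library(
    n: int,
    length: int = 18,
    base_probs: Sequence[float] = UNIFORM_PROBS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> UTRLibrary:
    """Virtual library of n i.i.d. random regions (the P.rand null)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = random_region_matrix(n, length, base_probs, rng)
    return UTRLibrary(decode_row(row) for row in mat)


def permute_library(
    library: UTRLibrary,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> UTRLibrary:
    """Shuffle each read's region independently (the P.perm null).

    Every read — including duplicate reads — is scrambled on its own, so the
    per-read base composition is exactly preserved while base order is
    destroyed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mat = library.expanded_matrix()
    if mat.size == 0:
        return UTRLibrary()
    shuffled = rng.permuted(mat, axis=1)
    return UTRLibrary(decode_row(row) for row in shuffled)


# ---------------------------------------------------------------------------
# empirical and analytic p-values
# ---------------------------------------------------------------------------

def empirical_pvalue(observed: int, null_counts: Sequence[int]) -> float:
    """Add-one upper-tail Monte-Carlo p-value.

    p = (1 + #{replicates with null >= observed}) / (N + 1), in (0, 1].
    """
    nulls = np.asarray(null_counts)
    if nulls.size == 0:
        raise ValueError("null_counts must be non-empty")
    exceed = int(np.count_nonzero(nulls >= observed))
    return (1 + exceed) / (nulls.size + 1)


def _kmp_automaton(pattern: np.ndarray) -> np.ndarray:
    """(k+1, 4) transition table of the substring-matching automaton.

    State s = length of the longest prefix of the pattern matching the
    current suffix; state k is absorbing (motif seen).
    """
    k = len(pattern)
    delta = np.zeros((k + 1, 4), dtype=np.int64)
    for c in range(4):
        delta[0, c] = 1 if k and pattern[0] == c else 0
    fail = 0
    for s in range(1, k):
        for c in range(4):
            delta[s, c] = s + 1 if pattern[s] == c else delta[fail, c]
        fail = delta[fail, pattern[s]]
    delta[k, :] = k
    return delta


def containment_probability(
    motif: str, length: int, base_probs: Sequence[float] = UNIFORM_PROBS
) -> float:
    """Exact probability that a random i.i.d. sequence contains the motif.

    Dynamic programming over the motif's failure-function automaton; exact up
    to floating round-off.  Returns 0 when the motif is longer than the
    sequence (documented convention).
    """
    from .alphabet import encode

    pattern = encode(motif)
    k = len(pattern)
    if k < 1:
        raise ValueError("motif must be non-empty")
    if k > length:
        return 0.0
    p = _validate_probs(base_probs)
    delta = _kmp_automaton(pattern)
    prob = np.zeros(k + 1)
    prob[0] = 1.0
    for _ in range(length):
        nxt = np.zeros(k + 1)
        for c in range(4):
            np.add.at(nxt, delta[:, c], prob * p[c])
        prob = nxt
    return float(prob[k])


def containment_probability_any(
    motifs: Iterable[str], length: int, base_probs: Sequence[float] = UNIFORM_PROBS
) -> float:
    """Exact probability of containing at least one of several motifs.

    Aho-Corasick automaton with failure links; the accepting super-state is
    absorbing.  Used both as the chance-SD-containment oracle and to
    calibrate the synthetic selected-library generator.
    """
    from .alphabet import encode

    patterns = [encode(m) for m in motifs]
    patterns = [p for p in patterns if len(p) <= length]
    if not patterns:
        return 0.0
    p = _validate_probs(base_probs)

    # trie construction
    goto: list[list[int]] = [[-1] * 4]
    accept = [False]
    for pat in patterns:
        state = 0
        for c in pat:
            if goto[state][c] == -1:
                goto.append([-1] * 4)
                accept.append(False)
                goto[state][c] = len(goto) - 1
            state = goto[state][c]
        accept[state] = True

    # BFS failure links -> full transition function
    n_states = len(goto)
    fail = [0] * n_states
    delta = np.zeros((n_states, 4), dtype=np.int64)
    queue: list[int] = []
    for c in range(4):
        nxt = goto[0][c]
        if nxt == -1:
            delta[0, c] = 0
        else:
            delta[0, c] = nxt
            fail[nxt] = 0
            queue.append(nxt)
    while queue:
        state = queue.pop(0)
        accept[state] = accept[state] or accept[fail[state]]
        for c in range(4):
            nxt = goto[state][c]
            if nxt == -1:
                delta[state, c] = delta[fail[state], c]
            else:
                delta[state, c] = nxt
                fail[nxt] = delta[fail[state], c]
                queue.append(nxt)

    # collapse accepting states into one absorbing state
    sink = n_states
    delta_abs = np.vstack([delta, np.full((1, 4), sink)])
    for s in range(n_states):
        if accept[s]:
            delta_abs[s, :] = sink
    prob = np.zeros(n_states + 1)
    prob[0] = 1.0
    for _ in range(length):
        nxt_p = np.zeros(n_states + 1)
        for c in range(4):
            np.add.at(nxt_p, delta_abs[:, c], prob * p[c])
        prob = nxt_p
    acc = prob[sink] + sum(prob[s] for s in range(n_states) if accept[s])
    return float(acc)


def containment_probabilities_all(
    k: int, length: int, base_probs: Sequence[float] = UNIFORM_PROBS
) -> np.ndarray:
    """Containment probability for every 4^k motif at once (vectorized DP)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > length:
        return np.zeros(4**k)
    p = _validate_probs(base_probs)
    M = 4**k
    # motif base matrix: P[m, j] = j-th base of motif m
    codes = np.arange(M, dtype=np.int64)
    P = np.zeros((M, k), dtype=np.int64)
    for j in range(k):
        P[:, j] = (codes >> (2 * (k - 1 - j))) & 3

    # per-motif KMP transition tables, built in lockstep across all motifs
    delta = np.zeros((M, k + 1, 4), dtype=np.int64)
    for c in range(4):
        delta[:, 0, c] = (P[:, 0] == c).astype(np.int64)
    fail = np.zeros(M, dtype=np.int64)
    rows = np.arange(M)
    for s in range(1, k):
        for c in range(4):
            fallback = delta[rows, fail, c]
            delta[:, s, c] = np.where(P[:, s] == c, s + 1, fallback)
        fail = delta[rows, fail, P[:, s]]
    delta[:, k, :] = k

    prob = np.zeros((M, k + 1))
    prob[:, 0] = 1.0
    for _ in range(length):
        nxt = np.zeros((M, k + 1))
        for s in range(k + 1):
            for c in range(4):
                np.add.at(nxt, (rows, delta[:, s, c]), prob[:, s] * p[c])
        prob = nxt
    return prob[:, k]


def expected_occurrences(
    motif: str, length: int, base_probs: Sequence[float] = UNIFORM_PROBS
) -> float:
    """Expected number of (possibly overlapping) occurrences per sequence."""
    p = _validate_probs(base_probs)
    s = normalize(motif)
    if len(s) > length:
        return 0.0
    from .alphabet import BASE_INDEX

    per_window = 1.0
    for c in s:
        per_window *= p[BASE_INDEX[c]]
    return (length - len(s) + 1) * per_window


def analytic_pvalue(observed: int, n: int, p_contain: float) -> float:
    """Upper-tail Binomial(n, p_contain) probability P(X >= observed)."""
    if not 0.0 <= p_contain <= 1.0:
        raise ValueError("p_contain must be in [0,1]")
    if not 0 <= observed <= n:
        raise ValueError("observed must be in [0, n]")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, p_contain))


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_bonferroni(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def adjust_fdr(ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("ps must be non-empty")
    return stats.false_discovery_control(ps, method="bh")


# ---------------------------------------------------------------------------
# replicate engine
# ---------------------------------------------------------------------------

def null_exceed_counts(
    library: UTRLibrary,
    k: int,
    observed: np.ndarray,
    config: NullModelConfig,
    *,
    motif_codes: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    occurrences: bool = False,
) -> np.ndarray:
    """Count replicates whose null incidence >= the observed incidence.

    One replicate library yields the full incidence vector for its k, so the
    same replicates serve every motif (or every rRNA window) of that k — the
    per-library counting scheme of the original analysis.

    Parameters
    ----------
    observed
        Incidence per motif: either the full 4^k vector, or, when
        ``motif_codes`` is given, the vector restricted to those codes.
    motif_codes
        Optional subset of motif codes to track (e.g. the reverse
        complements of rRNA windows).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = library.total
    L = library.region_length
    size = 4**k
    observed = np.asarray(observed, dtype=np.int64)
    exceed = np.zeros_like(observed)

    if config.kind == "permuted":
        base_mat = library.expanded_matrix()
    elif config.kind != "random_uniform":
        raise ValueError(f"unknown null kind {config.kind!r}")

    # batch replicates to amortize numpy overhead while bounding memory
    batch = max(1, min(config.replicates, 4_000_000 // max(1, n * L)))
    done = 0
    while done < config.replicates:
        b = min(batch, config.replicates - done)
        if config.kind == "random_uniform":
            flat = random_region_matrix(b * n, L, config.base_probs, rng)
        else:
            tiled = np.broadcast_to(base_mat, (b,) + base_mat.shape).reshape(b * n, L)
            flat = rng.permuted(tiled, axis=1)
        mats = flat.reshape(b, n, L)
        for r in range(b):
            inc = incidence_vector(mats[r], None, k, occurrences=occurrences)
            vals = inc if motif_codes is None else inc[motif_codes]
            exceed += vals >= observed
        done += b
    return exceed
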