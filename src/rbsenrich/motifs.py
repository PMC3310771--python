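"""Exhaustive k-mer motif search and co-occurrence analysis.

All 4^k motifs (k = 4..8) are scored by incidence — the number of library
members containing the motif at least once, multiplicity-weighted — and
tested for overrepresentation against the random-uniform and permuted
nulls.  p-values are converted to Benjamini-Hochberg q-values within each
4^k family (Q.rand / Q.perm); the significant set is {q < 0.01}.

The random null admits an exact alternative (``method="analytic"``): the
automaton containment probability feeds a binomial upper tail, equivalent
to infinitely many Monte-Carlo replicates.

Co-occurrence between significant motifs m1, m2 is the fraction of members
containing m2 that also contain a *non-overlapping* occurrence of m1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import normalize, to_dna
from .kmers import code_to_kmer, incidence_vector
from .library import UTRLibrary
from .nulls import (
    NullModelConfig,
    adjust_fdr,
    analytic_pvalue,
    containment_probabilities_all,
    null_exceed_counts,
)


@dataclass
class MotifSearchRecord:
    motif: str
    k: int
    incidence: int
    frequency: float
    q_rand: float | None = None
    q_perm: float | None = None


def motif_incidence_table(library: UTRLibrary, k: int) -> np.ndarray:
    """Incidence over all 4^k motifs (members containing >= 1 occurrence)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if library.total == 0:
        return np.zeros(4**k, dtype=np.int64)
    if k > library.region_length:
        raise ValueError("k exceeds region length")
    mat, weights = library.matrix()
    return incidence_vector(mat, weights, k)


def motif_significance(
    library: UTRLibrary,
    k: int,
    *,
    replicates: int = 1000,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    method: str = "empirical",
    include_perm: bool = True,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """q-values for every 4^k motif under the random (and permuted) nulls.

    ``method`` controls the random null: "empirical" (Monte-Carlo replicate
    libraries, add-one p-values) or "analytic" (exact containment
    probability + binomial tail).  The permuted null is always empirical.

    Returns a frame sorted by motif code with columns: motif, k, incidence,
    frequency, p_rand, q_rand[, p_perm, q_perm], significant.
    """
    if library.total == 0:
        raise ValueError("library must be non-empty")
    n = library.total
    observed = motif_incidence_table(library, k)
    ss = np.random.SeedSequence(seed)
    rng_rand, rng_perm = (np.random.default_rng(c) for c in ss.spawn(2))

    if method == "analytic":
        p_contain = containment_probabilities_all(k, library.region_length, base_probs)
        p_rand = np.array(
            [analytic_pvalue(int(o), n, p) for o, p in zip(observed, p_contain)]
        )
    elif method == "empirical":
        cfg = NullModelConfig("random_uniform", replicates, tuple(base_probs))
        exceed = null_exceed_counts(library, k, observed, cfg, rng=rng_rand)
        p_rand = (1 + exceed) / (replicates + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(
        {
            "motif": [code_to_kmer(c, k) for c in range(4**k)],
            "k": k,
            "incidence": observed,
            "frequency": observed / n,
            "p_rand": p_rand,
            "q_rand": adjust_fdr(p_rand),
        }
    )
    if include_perm:
        cfg = NullModelConfig("permuted", replicates)
        exceed = null_exceed_counts(library, k, observed, cfg, rng=rng_perm)
        out["p_perm"] = (1 + exceed) / (replicates + 1)
        out["q_perm"] = adjust_fdr(out["p_perm"])
    out["significant"] = out["q_rand"] < fdr
    return out


def top_motifs(
    records: pd.DataFrame | Iterable[MotifSearchRecord | tuple[str, float]],
    m: int,
) -> list[tuple[str, float]]:
    """Top-m motifs by frequency, ties broken lexicographically."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if isinstance(records, pd.DataFrame):
        pairs = list(zip(records["motif"], records["frequency"]))
    else:
        pairs = [
            (r.motif, r.frequency) if isinstance(r, MotifSearchRecord) else tuple(r)
            for r in records
        ]
    pairs.sort(key=lambda mf: (-mf[1], mf[0]))
    return pairs[:m]


def _motif_only(entry) -> str:
    if isinstance(entry, str):
        return to_dna(normalize(entry))
    return to_dna(normalize(entry[0]))


def compare_motif_lists(
    list_a: Sequence, list_b: Sequence, top_a: int | None = None, top_b: int | None = None
) -> list[str]:
    """Motifs shared between the first top_a of A and first top_b of B.

    Entries may be plain motifs or (motif, frequency) pairs; U/T rendering
    is normalized before comparison.  Order preserved by A's ranking; the
    returned motifs keep A's rendering.
    """
    a = list(list_a)[: top_a if top_a is not None else len(list_a)]
    b = list(list_b)[: top_b if top_b is not None else len(list_b)]
    b_set = {_motif_only(e) for e in b}
    shared = []
    for entry in a:
        key = _motif_only(entry)
        if key in b_set:
            shared.append(entry if isinstance(entry, str) else entry[0])
    return shared


def _occurrence_offsets(seq: str, motif: str) -> list[int]:
    offsets, start = [], 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return offsets
        offsets.append(i)
        start = i + 1  # overlapping occurrences allowed


def count_nonoverlapping_pair(region: str, motif1: str, motif2: str) -> bool:
    """True iff the region holds occurrences of both motifs on disjoint spans.

    When motif1 == motif2 two disjoint occurrences are required.
    """
    seq = normalize(region)
    m1, m2 = to_dna(normalize(motif1)), to_dna(normalize(motif2))
    occ1 = _occurrence_offsets(seq, m1)
    if not occ1:
        return False
    occ2 = _occurrence_offsets(seq, m2)
    for i in occ1:
        for j in occ2:
            if j >= i + len(m1) or i >= j + len(m2):
                return True
    return False


@dataclass
class CooccurrenceRecord:
    motif1: str
    motif2: str
    coincidence: int
    denominator: int

    @property
    def metric(self) -> float:
        return self.coincidence / self.denominator


def cooccurrence_table(
    library: UTRLibrary, significant_motifs: Sequence[str]
) -> pd.DataFrame:
    """Ordered-pair co-occurrence among significant motifs (any k mixed).

    metric(m1, m2) = #{members with non-overlapping m1 and m2}
                     / #{members containing m2};
    pairs with zero coincidence or zero denominator are omitted, as are
    self-pairs.
    """
    motifs = [to_dna(normalize(m)) for m in significant_motifs]
    counts = library.counts()
    containing = {
        m: sum(mult for seq, mult in counts.items() if m in seq) for m in motifs
    }
    rows = []
    for m1 in motifs:
        for m2 in motifs:
            if m1 == m2 or containing[m2] == 0:
                continue
            coincidence = sum(
                mult
                for seq, mult in counts.items()
                if count_nonoverlapping_pair(seq, m1, m2)
            )
            if coincidence == 0:
                continue
            rows.append(
                {
                    "motif1": m1,
                    "motif2": m2,
                    "coincidence": coincidence,
                    "denominator": containing[m2],
                    "metric": coincidence / containing[m2],
                }
            )
    return pd.DataFrame(rows, columns=["motif1", "motif2", "coincidence", "denominator", "metric"])


def records_from_frame(frame: pd.DataFrame) -> list[MotifSearchRecord]:
    return [
        MotifSearchRecord(
            motif=row.motif,
            k=int(row.k),
            incidence=int(row.incidence),
            frequency=float(row.frequency),
            q_rand=float(row.q_rand) if "q_rand" in frame.columns else None,
            q_perm=float(row.q_perm) if "q_perm" in frame.columns else None,
        )
        for row in frame.itertuples()
    ]
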