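"""Sliding-window secondary-structure scoring.

Each library region is embedded in a 70-base mRNA context (26 bases
upstream, the 18-base region, 26 bases from the start codon onward) and cut
into five overlapping 30-base windows with a 10-base offset.  Each window is
scored with a deliberately simple folding model:

    minimum free energy over nested pairings (Watson-Crick + G:U), where
    consecutive ("stacked") pairs contribute a nearest-neighbour stack
    energy from a small embedded table, hairpin loops keep >= 3 unpaired
    bases, and isolated pairs contribute 0.

This is a stacking-energy Zuker-style recursion without multiloop, bulge or
dangle terms.  It supports distribution-shape comparisons between a library
and a simulated random library; it is not a thermodynamic parity model, and
a callable hook (``folder=``) lets users substitute any external
sequence->dG folder.  Scores are in kcal/mol, <= 0, 0 = unstructured.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .alphabet import normalize
from .library import UTRLibrary
from .nulls import random_region_matrix
from .alphabet import decode_row

#: Synthetic default flanks.  The 10 bases adjacent to the randomized region
#: reproduce the fixed amplicon flanks (TGTTTAACTT / ATGGCGGACT, the latter
#: beginning with the start codon); the outer 16 bases on each side are
#: synthetic vector-style padding, not data from any published construct.
DEFAULT_UPSTREAM26 = "CAACGGTTTCCCTCTA" + "TGTTTAACTT"
DEFAULT_DOWNSTREAM26 = "ATGGCGGACT" + "ACAAGGACGACGATGA"

_GU_STACK = -0.5  # flat stack term for any stack involving a G:U pair

# Watson-Crick nearest-neighbour stack free energies (kcal/mol, 37 C),
# keyed (outer pair 5'base+3'base, inner pair).  DNA letters; T == U.
_WC_STACKS = {
    ("AT", "AT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("CG", "TA"): -2.08,
    ("CG", "AT"): -2.11,
    ("GC", "TA"): -2.24,
    ("GC", "AT"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
}

_PAIR_OK = {"AT", "TA", "GC", "CG"}
_PAIR_GU = {"GT", "TG"}


def _build_stack_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    pairs = list(_PAIR_OK | _PAIR_GU)
    for key, e in _WC_STACKS.items():
        table[key] = e
        # strand symmetry: stack(p, q) == stack(reverse(q), reverse(p))
        table[(key[1][::-1], key[0][::-1])] = e
    for p in pairs:
        for q in pairs:
            if p in _PAIR_GU or q in _PAIR_GU:
                table[(p, q)] = _GU_STACK
    return table


STACK_TABLE = _build_stack_table()

MIN_HAIRPIN = 3  # unpaired bases enclosed by a hairpin-closing pair


@dataclass(frozen=True)
class AssembledMolecule:
    """70-base mRNA: upstream26 + region18 + downstream26."""

    id: str
    bases: str
    region_start: int = 26
    region_length: int = 18


@dataclass
class StructureWindowRecord:
    molecule_id: str
    ordinal: int  # 1..5
    start: int  # 0-based offset in the molecule
    dG: float


def assemble_molecule(
    region: str,
    upstream26: str = DEFAULT_UPSTREAM26,
    downstream26: str = DEFAULT_DOWNSTREAM26,
    molecule_id: str = "mol",
) -> AssembledMolecule:
    up, down, reg = normalize(upstream26), normalize(downstream26), normalize(region)
    if len(up) != 26 or len(down) != 26:
        raise ValueError("flanking pieces must be exactly 26 bases")
    if len(reg) != 18:
        raise ValueError("region must be exactly 18 bases")
    return AssembledMolecule(id=molecule_id, bases=up + reg + down)


def sliding_windows(
    molecule: AssembledMolecule | str, size: int = 30, offset: int = 10
) -> list[tuple[int, str]]:
    """(start, window) pairs tiling the molecule exactly (default: 5 windows)."""
    bases = molecule.bases if isinstance(molecule, AssembledMolecule) else normalize(molecule)
    if size > len(bases):
        raise ValueError("window size exceeds molecule length")
    if (len(bases) - size) % offset != 0:
        implied = (len(bases) - size) / offset + 1
        raise ValueError(
            f"geometry does not tile exactly (implied window count {implied:.2f})"
        )
    n_windows = (len(bases) - size) // offset + 1
    return [(i * offset, bases[i * offset : i * offset + size]) for i in range(n_windows)]


def _pairable(a: str, b: str, allow_gu: bool) -> bool:
    pair = a + b
    return pair in _PAIR_OK or (allow_gu and pair in _PAIR_GU)


def fold_dG(
    window: str,
    *,
    allow_gu: bool = True,
    folder: Callable[[str], float] | None = None,
) -> float:
    """Minimum free energy of one window under the built-in model.

    ``folder`` overrides the built-in model with an external
    sequence -> dG callable (e.g. a wrapper around a full thermodynamic
    folder); the sequence is passed in DNA rendering.
    """
    s = normalize(window)
    if folder is not None:
        return float(folder(s))
    n = len(s)
    if n < MIN_HAIRPIN + 2:
        return 0.0
    INF = float("inf")
    V = np.full((n, n), INF)
    W = np.zeros((n, n))
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            if _pairable(s[i], s[j], allow_gu):
                best = W[i + 1, j - 1]  # isolated pair closes any interior
                if (
                    j - i - 2 > MIN_HAIRPIN
                    and _pairable(s[i + 1], s[j - 1], allow_gu)
                    and V[i + 1, j - 1] < INF
                ):
                    stack = STACK_TABLE[(s[i] + s[j], s[i + 1] + s[j - 1])]
                    best = min(best, V[i + 1, j - 1] + stack)
                V[i, j] = best
            w = min(W[i + 1, j], W[i, j - 1], V[i, j])
            if span >= 2:
                bif = np.min(W[i, i : j] + W[i + 1 : j + 1, j])
                w = min(w, bif)
            W[i, j] = w
    return float(min(0.0, W[0, n - 1]))


def window_records(
    library: UTRLibrary,
    upstream26: str = DEFAULT_UPSTREAM26,
    downstream26: str = DEFAULT_DOWNSTREAM26,
    *,
    folder: Callable[[str], float] | None = None,
) -> pd.DataFrame:
    """Per-member, per-window dG (one row per unique member and window;
    multiplicity carried in its own column)."""
    rows = []
    for i, (seq, mult) in enumerate(library.counts().items(), start=1):
        mol = assemble_molecule(seq, upstream26, downstream26, molecule_id=f"mol_{i}")
        for ordinal, (start, win) in enumerate(sliding_windows(mol), start=1):
            rows.append(
                {
                    "molecule_id": mol.id,
                    "region": seq,
                    "multiplicity": mult,
                    "ordinal": ordinal,
                    "start": start,
                    "dG": fold_dG(win, folder=folder),
                }
            )
    return pd.DataFrame(rows)


def dG_profile(
    library: UTRLibrary,
    upstream26: str = DEFAULT_UPSTREAM26,
    downstream26: str = DEFAULT_DOWNSTREAM26,
    *,
    simulated_n: int = 10_000,
    seed: int = 0,
    bin_width: float = 1.0,
    folder: Callable[[str], float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-window dG histograms for the library vs a simulated random library.

    The simulated library has i.i.d. uniform 18-base regions in the same
    flank context (default desk-scale 10,000; the original analysis used
    350,000).  Returns {"library": ..., "simulated": ..., "summary": ...};
    histograms are multiplicity-weighted, binned at ``bin_width`` kcal/mol.
    """
    if simulated_n < 1:
        raise ValueError("simulated_n must be >= 1")
    rng = np.random.default_rng(seed)
    sim = UTRLibrary(
        decode_row(r)
        for r in random_region_matrix(simulated_n, 18, (0.25,) * 4, rng)
    )
    lib_rec = window_records(library, upstream26, downstream26, folder=folder)
    sim_rec = window_records(sim, upstream26, downstream26, folder=folder)

    def hist(rec: pd.DataFrame) -> pd.DataFrame:
        out = []
        lo = np.floor(min(rec["dG"].min(), -1.0) / bin_width) * bin_width
        edges = np.arange(lo, 0.0 + bin_width, bin_width)
        for ordinal, grp in rec.groupby("ordinal"):
            counts, _ = np.histogram(
                grp["dG"], bins=edges, weights=grp["multiplicity"]
            )
            for left, c in zip(edges[:-1], counts):
                out.append(
                    {"ordinal": ordinal, "bin_left": left, "bin_right": left + bin_width,
                     "members": int(c)}
                )
        return pd.DataFrame(out)

    def summary(rec: pd.DataFrame, label: str) -> pd.DataFrame:
        rows = []
        for ordinal, grp in rec.groupby("ordinal"):
            vals = np.repeat(grp["dG"].to_numpy(), grp["multiplicity"].to_numpy())
            rows.append(
                {
                    "set": label,
                    "ordinal": ordinal,
                    "median_dG": float(np.median(vals)),
                    "q25_dG": float(np.quantile(vals, 0.25)),
                    "q75_dG": float(np.quantile(vals, 0.75)),
                }
            )
        return pd.DataFrame(rows)

    return {
        "library": hist(lib_rec),
        "simulated": hist(sim_rec),
        "library_records": lib_rec,
        "simulated_records": sim_rec,
        "summary": pd.concat(
            [summary(lib_rec, "library"), summary(sim_rec, "simulated")],
            ignore_index=True,
        ),
    }
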