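"""Synthetic RBS library generator.

The original 454 sequencing pools were never deposited, so this module
generates stand-in libraries whose summary statistics match what the
selection produced, making every downstream stage testable end to end:

* a *naive* library — i.i.d. random regions (the N18 starting pool, base
  probability 0.25 each);
* a *selected* library — a round-3-like mixture in which ~24% of members
  carry a Shine-Dalgarno motif planted at a position-biased offset, and the
  remaining ~76% are cytosine-rich, calibrated so that 61% of non-SD members
  carry nine or more cytosines out of 18.

The planting fraction is calibrated analytically: C-rich background draws
contain an SD motif by chance with probability q (exact Aho-Corasick
containment), so planting at f = (sd_fraction - q) / (1 - q) makes the
*observed* SD-classified fraction equal sd_fraction.  With sd_fraction=0 the
generator degenerates to a pure background draw whose chance SD level is q
itself.

Ground truth (original region, substitution and indel bookkeeping) rides in
the read identifiers so that a wrapped library is a single self-describing
artifact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .alphabet import DNA_BASES, decode_row, encode, normalize
from .library import UTRLibrary
from .nulls import (
    containment_probability_any,
    random_region_matrix,
    _validate_probs,
)
from .reads import ReadTemplate, SequenceRead

#: SD motif set used for classification (AGGU rendered as DNA).
SD_CORE_MOTIFS = ("AAGG", "AGGA", "GGAG", "GAGG", "AGGT")

#: Region offset at which the first base of a planted SD motif is centred.
#: The strongest positional enrichment sits around position -12, i.e. offset
#: 6 of the 18-base region counted from its 5' end.
DEFAULT_SD_CENTER_OFFSET = 6


def default_sd_position_distribution(
    region_length: int = 18,
    motif_length: int = 4,
    center: int = DEFAULT_SD_CENTER_OFFSET,
    sigma: float = 2.0,
) -> np.ndarray:
    """Discretized Gaussian over valid start offsets, zero elsewhere."""
    n_offsets = region_length - motif_length + 1
    offsets = np.arange(region_length, dtype=float)
    w = np.exp(-0.5 * ((offsets - center) / sigma) ** 2)
    w[n_offsets:] = 0.0
    return w / w.sum()


@lru_cache(maxsize=None)
def c_probability_for_tail(
    target: float = 0.61, min_c: int = 9, length: int = 18
) -> float:
    """Cytosine probability p with P(Binomial(length, p) >= min_c) = target.

    Solved on the exact binomial survival function; this is the calibration
    behind the default C-rich composition (61% of non-SD members with >= 9
    cytosines out of 18).
    """
    def tail(p: float) -> float:
        return float(stats.binom.sf(min_c - 1, length, p)) - target

    return float(optimize.brentq(tail, 1e-6, 1 - 1e-6, xtol=1e-12))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic library generator.

    ``crich_c_prob=None`` selects the calibrated default (~0.507, the exact
    binomial solution of the 61%-with->=9-C condition).
    """

    library_size: int
    region_length: int = 18
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sd_fraction: float = 0.24
    sd_motif_weights: dict[str, float] | None = None
    sd_position_distribution: tuple[float, ...] | None = None
    crich_c_prob: float | None = None
    planted_motifs: tuple[tuple[str, float], ...] = ()
    error_rate: float = 0.0
    length_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        _validate_probs(self.base_probs)
        for name in ("sd_fraction", "error_rate", "length_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.crich_c_prob is not None and not 0.0 <= self.crich_c_prob <= 1.0:
            raise ValueError("crich_c_prob must be in [0,1]")
        for motif, frac in self.planted_motifs:
            if len(normalize(motif)) > self.region_length:
                raise ValueError(f"planted motif {motif!r} longer than region")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planted motif fraction must be in [0,1]")
        if self.sd_position_distribution is not None:
            d = np.asarray(self.sd_position_distribution, dtype=float)
            if np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
                raise ValueError("sd_position_distribution must be a distribution")

    # -- derived pieces -------------------------------------------------
    def resolved_c_prob(self) -> float:
        if self.crich_c_prob is not None:
            return self.crich_c_prob
        return c_probability_for_tail(0.61, 9, self.region_length)

    def crich_probs(self) -> tuple[float, float, float, float]:
        """C fixed at crich_c_prob, remaining mass split per base_probs over A,G,T."""
        c = self.resolved_c_prob()
        others = np.array([self.base_probs[0], self.base_probs[2], self.base_probs[3]])
        if others.sum() <= 0:
            others = np.ones(3)
        others = others / others.sum() * (1 - c)
        return (float(others[0]), c, float(others[1]), float(others[2]))

    def resolved_motif_weights(self) -> tuple[tuple[str, float], ...]:
        if self.sd_motif_weights:
            items = [(normalize(m), float(w)) for m, w in self.sd_motif_weights.items()]
        else:
            items = [(m, 1.0) for m in SD_CORE_MOTIFS]
        total = sum(w for _, w in items)
        if total <= 0:
            raise ValueError("sd_motif_weights must have positive total weight")
        for m, _ in items:
            if len(m) > self.region_length:
                raise ValueError(f"SD motif {m!r} longer than region")
        return tuple((m, w / total) for m, w in items)

    def position_distribution_for(self, motif_length: int) -> np.ndarray:
        n_offsets = self.region_length - motif_length + 1
        if self.sd_position_distribution is not None:
            d = np.asarray(self.sd_position_distribution, dtype=float)
            if d[n_offsets:].sum() > 1e-12:
                raise ValueError(
                    "sd_position_distribution puts mass on offsets where the "
                    "motif would overrun the region"
                )
            return d[:n_offsets] / d[:n_offsets].sum()
        return default_sd_position_distribution(
            self.region_length, motif_length
        )[:n_offsets]


def generate_naive_library(config: GeneratorConfig) -> UTRLibrary:
    """Pure i.i.d. library (the N18 pool); SD/planting options are ignored."""
    rng = np.random.default_rng(config.seed)
    mat = random_region_matrix(
        config.library_size, config.region_length, config.base_probs, rng
    )
    return UTRLibrary(decode_row(row) for row in mat)


def generate_selected_library(config: GeneratorConfig) -> UTRLibrary:
    """Round-3-like mixture of planted-SD and C-rich members."""
    rng = np.random.default_rng(config.seed)
    n = config.library_size
    L = config.region_length
    crich = config.crich_probs()

    q = containment_probability_any(SD_CORE_MOTIFS, L, crich)
    if config.sd_fraction >= 1.0:
        f_plant = 1.0
    else:
        f_plant = max(0.0, (config.sd_fraction - q) / (1.0 - q))

    is_sd = rng.random(n) < f_plant
    mat = np.empty((n, L), dtype=np.uint8)
    n_sd = int(is_sd.sum())
    if n_sd:
        mat[is_sd] = random_region_matrix(n_sd, L, config.base_probs, rng)
    if n - n_sd:
        mat[~is_sd] = random_region_matrix(n - n_sd, L, crich, rng)

    # plant one SD motif per SD member at a position-biased offset
    weights = config.resolved_motif_weights()
    motif_strings = [m for m, _ in weights]
    motif_probs = np.array([w for _, w in weights])
    sd_rows = np.flatnonzero(is_sd)
    if sd_rows.size:
        choice = rng.choice(len(motif_strings), size=sd_rows.size, p=motif_probs)
        for row, mi in zip(sd_rows, choice):
            motif = encode(motif_strings[mi])
            pos_dist = config.position_distribution_for(len(motif))
            offset = rng.choice(len(pos_dist), p=pos_dist)
            mat[row, offset : offset + len(motif)] = motif

    # forced extra motifs, applied after the mixture draw
    for motif, frac in config.planted_motifs:
        pat = encode(motif)
        count = int(round(frac * n))
        if count == 0:
            continue
        rows = rng.choice(n, size=count, replace=False)
        offsets = rng.integers(0, L - len(pat) + 1, size=count)
        for row, off in zip(rows, offsets):
            mat[row, off : off + len(pat)] = pat

    return UTRLibrary(decode_row(row) for row in mat)


def wrap_reads(
    library: UTRLibrary,
    template: ReadTemplate | None = None,
    config: GeneratorConfig | None = None,
) -> list[SequenceRead]:
    """Embed each region in the fixed flank context, with optional errors.

    Read identifiers record ground truth:
    ``sim_<i>|region=<original>|indel=<-1|0|1>|nsub_flank=<n>|nsub_region=<n>``
    where substitution counts refer to the 10-base flanks and the (post-
    indel) randomized region of the finished read.
    """
    if template is None:
        template = ReadTemplate()
    error_rate = config.error_rate if config else 0.0
    length_error_rate = config.length_error_rate if config else 0.0
    seed = config.seed if config else 0
    rng = np.random.default_rng(seed + 1_000_003)

    if library.total == 0:
        raise ValueError("library must be non-empty")

    reads: list[SequenceRead] = []
    up = template.extra_upstream + template.upstream_flank
    for i, region in enumerate(library.expand()):
        reg = region
        indel = 0
        if length_error_rate and rng.random() < length_error_rate:
            if rng.random() < 0.5 and len(reg) > 1:
                indel = -1
                pos = int(rng.integers(0, len(reg)))
                reg = reg[:pos] + reg[pos + 1 :]
            else:
                indel = +1
                pos = int(rng.integers(0, len(reg) + 1))
                reg = reg[:pos] + DNA_BASES[rng.integers(0, 4)] + reg[pos:]
        bases = up + reg + template.downstream_flank + template.extra_downstream
        nsub_flank = nsub_region = 0
        if error_rate:
            arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
            up_span = (len(template.extra_upstream), len(up))
            reg_span = (len(up), len(up) + len(reg))
            down_span = (reg_span[1], reg_span[1] + len(template.downstream_flank))
            for pos in hits:
                old = chr(arr[pos])
                alternatives = [b for b in DNA_BASES if b != old]
                arr[pos] = ord(alternatives[rng.integers(0, 3)])
                if up_span[0] <= pos < up_span[1] or down_span[0] <= pos < down_span[1]:
                    nsub_flank += 1
                elif reg_span[0] <= pos < reg_span[1]:
                    nsub_region += 1
            bases = arr.tobytes().decode("ascii")
        reads.append(
            SequenceRead(
                id=(
                    f"sim_{i}|region={region}|indel={indel}"
                    f"|nsub_flank={nsub_flank}|nsub_region={nsub_region}"
                ),
                bases=bases,
            )
        )
    return reads


def parse_ground_truth(read_id: str) -> dict[str, str | int]:
    """Decode the bookkeeping fields written by :func:`wrap_reads`."""
    fields = read_id.split("|")
    truth: dict[str, str | int] = {"name": fields[0]}
    for tok in fields[1:]:
        key, value = tok.split("=", 1)
        truth[key] = value if key == "region" else int(value)
    return truth


def theoretical_diversity(region_length: int = 18) -> int:
    """Number of distinct fully randomized regions, 4**L (6.9e10 for L=18)."""
    return 4**region_length


def sci_notation(x: float, sig: int = 2) -> str:
    """Render like '6.9e+10' at the given number of significant digits."""
    return f"{x:.{sig - 1}e}"
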