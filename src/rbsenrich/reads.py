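"""Locating and filtering the randomized region in sequencing reads.

Each read from the selection amplicon carries an 18-base randomized region
between two fixed 10-base flanks (``TGTTTAACTT`` upstream, ``ATGGCGGACT``
downstream — the downstream flank begins with the start codon).  A read is
accepted only if

1. both flanks occur exactly (any error in the 10 bases on either side of
   the randomized region rejects the read),
2. the enclosed span is exactly the configured region length, and
3. the region contains no codon-aligned ATG that could act as an alternate
   start site (frame anchored to the downstream start codon).

Rejection categories count the first failing rule, so the categories
partition the input exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .alphabet import normalize
from .library import UTRLibrary, _open_text


@dataclass
class SequenceRead:
    """One raw read; U is normalized to T on construction."""

    id: str
    bases: str
    quality: str | None = None

    def __post_init__(self):
        self.bases = normalize(self.bases, allow_n=True)
        if not self.bases:
            raise ValueError("read has no bases")


@dataclass(frozen=True)
class ReadTemplate:
    """Fixed sequence context around the randomized region."""

    upstream_flank: str = "TGTTTAACTT"
    downstream_flank: str = "ATGGCGGACT"
    extra_upstream: str = ""
    extra_downstream: str = ""

    def __post_init__(self):
        for name in ("upstream_flank", "downstream_flank"):
            flank = normalize(getattr(self, name))
            if not flank:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, flank)
        object.__setattr__(self, "extra_upstream", normalize(self.extra_upstream))
        object.__setattr__(self, "extra_downstream", normalize(self.extra_downstream))


@dataclass
class FilterReport:
    """Per-category read accounting; categories partition total_reads."""

    total_reads: int = 0
    accepted: int = 0
    rejected_length: int = 0
    rejected_flank: int = 0
    rejected_inframe_start: int = 0
    rejected_no_locus: int = 0
    unique_accepted: int = 0

    def check_partition(self) -> None:
        parts = (
            self.accepted
            + self.rejected_length
            + self.rejected_flank
            + self.rejected_inframe_start
            + self.rejected_no_locus
        )
        if parts != self.total_reads:
            raise AssertionError(
                f"category counts {parts} != total reads {self.total_reads}"
            )

    def to_tsv(self, path: str | Path) -> None:
        fields = [
            "total_reads",
            "accepted",
            "rejected_length",
            "rejected_flank",
            "rejected_inframe_start",
            "rejected_no_locus",
            "unique_accepted",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(fields) + "\n")
            fh.write("\t".join(str(getattr(self, f)) for f in fields) + "\n")


class LocateFailure(Exception):
    """A flank could not be found exactly in the read."""

    def __init__(self, category: str):
        self.category = category
        super().__init__(category)


def locate_randomized_region(
    read: SequenceRead, template: ReadTemplate
) -> tuple[int, int]:
    """Half-open interval of the span between the two flanks.

    The first exact occurrence of the upstream flank and the first exact
    occurrence of the downstream flank after it delimit the region.  The
    enclosed span may be any length; length checking is a separate rule.

    Raises
    ------
    LocateFailure
        ``no_locus`` if the upstream flank is absent, ``flank`` if the
        downstream flank is absent after it.
    """
    up = read.bases.find(template.upstream_flank)
    if up < 0:
        raise LocateFailure("no_locus")
    start = up + len(template.upstream_flank)
    down = read.bases.find(template.downstream_flank, start)
    if down < 0:
        raise LocateFailure("flank")
    return start, down


def has_inframe_start(region: str, region_length: int | None = None) -> bool:
    """True iff ATG occurs codon-aligned with the downstream start codon.

    For the default 18-base region (18 = 0 mod 3) that means 0-based offsets
    0, 3, 6, 9, 12, 15.
    """
    region = normalize(region, allow_n=True)
    L = region_length if region_length is not None else len(region)
    if L % 3 != 0:
        raise ValueError(
            "region length not divisible by 3: frame anchoring to the "
            "downstream start codon is ambiguous"
        )
    return any(region[o : o + 3] == "ATG" for o in range(0, len(region) - 2, 3))


def filter_reads(
    reads: Iterable[SequenceRead],
    template: ReadTemplate | None = None,
    region_length: int = 18,
) -> tuple[UTRLibrary, FilterReport]:
    """Apply the exclusion rules in order: locate, length, in-frame ATG.

    Regions containing ambiguous bases (N) after location are counted under
    ``rejected_length`` (the region could not be read as 18 unambiguous
    bases).
    """
    if template is None:
        template = ReadTemplate()
    library = UTRLibrary()
    report = FilterReport()
    for read in reads:
        report.total_reads += 1
        try:
            start, end = locate_randomized_region(read, template)
        except LocateFailure as exc:
            if exc.category == "no_locus":
                report.rejected_no_locus += 1
            else:
                report.rejected_flank += 1
            continue
        region = read.bases[start:end]
        if len(region) != region_length or "N" in region:
            report.rejected_length += 1
            continue
        if has_inframe_start(region):
            report.rejected_inframe_start += 1
            continue
        report.accepted += 1
        library.add(region)
    report.unique_accepted = library.n_unique
    report.check_partition()
    return library, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[SequenceRead]:
    """Read FASTA or FASTQ (gzip-transparent); format inferred from suffix."""
    path = Path(path)
    if fmt is None:
        suffixes = [s.lower() for s in path.suffixes]
        stem = [s for s in suffixes if s != ".gz"]
        last = stem[-1] if stem else ""
        fmt = "fastq" if last in (".fastq", ".fq") else "fasta"
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield SequenceRead(id=rec.description, bases=str(rec.seq), quality=qual)


def write_reads(reads: Iterable[SequenceRead], path: str | Path, fmt: str = "fasta") -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            if fmt == "fasta":
                handle.write(f">{read.id}\n{read.bases}\n")
            elif fmt == "fastq":
                qual = read.quality or "I" * len(read.bases)
                handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")
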