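"""Sequence and interval I/O with a fixed coordinate convention.

All coordinates in this package are 0-based half-open (BED convention).
Inputs in 1-based inclusive coordinates (NUCmer ``show-coords`` tables) are
converted at the parser boundary and never seen downstream.

The FASTA and BED readers are deliberately line-aware so that format errors
can name the offending line; both formats are line-oriented, which makes the
validation and the parse the same pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import BoundsError, FormatError

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named chromosome sequence over the alphabet {A, C, G, T, N}.

    Sequences are stored uppercase; lowercase input (soft-masked FASTA) is
    accepted and normalized on construction.
    """

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.name!r} contains illegal characters: "
                + ",".join(sorted(bad))
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 when disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of :class:`SequenceRecord`.

    Wrapped and unwrapped sequence lines are both accepted; duplicate record
    names are rejected. Errors name the 1-based line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    name_line = 0

    def flush():
        if name is None:
            return
        if name in seen:
            raise FormatError(f"duplicate record name {name!r}", path, name_line)
        seen.add(name)
        seq = "".join(chunks).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"illegal characters in record {name!r}: " + ",".join(sorted(bad)),
                path,
                name_line,
            )
        records.append(SequenceRecord(name, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError("empty FASTA header", path, lineno)
                name_line = lineno
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        "sequence data before first FASTA header", path, lineno
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def genome_lengths(records: Iterable[SequenceRecord]) -> dict[str, int]:
    return {rec.name: len(rec) for rec in records}


# ---------------------------------------------------------------------------
# BED and NUCmer coords


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3/BED4 file; output is sorted per chromosome.

    The optional 4th column becomes the interval label.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED line has fewer than 3 columns", path, lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", path, lineno) from None
            if start >= end:
                raise FormatError(
                    f"empty or inverted interval {chrom}:{start}-{end}", path, lineno
                )
            if start < 0:
                raise FormatError("negative BED start", path, lineno)
            label = fields[3] if len(fields) >= 4 else None
            intervals.append(GenomicInterval(chrom, start, end, label))
    return sorted(intervals)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED3 (BED4 when a label is present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")


def read_nucmer_coords(path) -> list[GenomicInterval]:
    """Import a NUCmer ``show-coords -T`` style TSV of reference hits.

    The first two columns are the reference start and end, 1-based inclusive;
    they are converted to 0-based half-open here. The chromosome name is taken
    from the last column of each row (show-coords -T places the reference tag
    there for single-reference output) unless the row has exactly three
    columns (chrom, start, end).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # Header lines of show-coords output are not numeric; skip them.
            try:
                if len(fields) == 3:
                    chrom, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                else:
                    s1, e1 = int(fields[0]), int(fields[1])
                    chrom = fields[-1]
            except ValueError:
                continue
            if s1 > e1:  # reverse-strand hit; reference span is still s1..e1
                s1, e1 = e1, s1
            if s1 < 1:
                raise FormatError("1-based coordinate below 1", path, lineno)
            intervals.append(GenomicInterval(chrom, s1 - 1, e1))
    return sorted(intervals)


# ---------------------------------------------------------------------------
# Interval algebra (all operations merge their inputs first)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or exactly bookended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom, group in itertools.groupby(sorted(intervals), key=lambda iv: iv.chrom):
        cur_start = cur_end = None
        for iv in group:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def coverage(intervals: Iterable[GenomicInterval]) -> int:
    """Total base coverage (bp) of the merged interval set."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def complement_regions(
    regions: Iterable[GenomicInterval],
    genome: Iterable[SequenceRecord] | dict[str, int],
) -> list[GenomicInterval]:
    """Per-chromosome set complement of ``regions`` against the genome.

    Chromosomes absent from ``regions`` yield one full-length interval.
    N runs are not treated specially: the complement is purely positional.
    """
    lengths = genome if isinstance(genome, dict) else genome_lengths(genome)
    merged = merge_intervals(regions)
    for iv in merged:
        if iv.chrom not in lengths:
            raise BoundsError(f"region on unknown chromosome {iv.chrom!r}")
        if iv.end > lengths[iv.chrom]:
            raise BoundsError(
                f"region {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {lengths[iv.chrom]}"
            )
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in lengths:
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = iv.end
        if pos < lengths[chrom]:
            out.append(GenomicInterval(chrom, pos, lengths[chrom]))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two interval sets (merged on both sides)."""
    a_merged, b_merged = merge_intervals(a), merge_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        for jv in by_chrom_b.get(iv.chrom, []):
            lo, hi = max(iv.start, jv.start), min(iv.end, jv.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return sorted(out)


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level difference cov(a) minus cov(b)."""
    a_merged, b_merged = merge_intervals(a), merge_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        pos = iv.start
        for jv in by_chrom_b.get(iv.chrom, []):
            if jv.end <= pos or jv.start >= iv.end:
                continue
            if jv.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, jv.start))
            pos = max(pos, jv.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return sorted(out)


def check_bounds(
    intervals: Sequence[GenomicInterval],
    genome: Iterable[SequenceRecord] | dict[str, int],
) -> None:
    """Raise :class:`BoundsError` if any interval exceeds its chromosome."""
    lengths = genome if isinstance(genome, dict) else genome_lengths(genome)
    for iv in intervals:
        if iv.chrom not in lengths or iv.end > lengths[iv.chrom]:
            raise BoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} out of genome bounds"
            )
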