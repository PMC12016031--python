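"""Divergence arithmetic and overlap partitions between island sets.

All length bookkeeping is over merged base coverage, not record counts:
overlapping or bookended intervals within a set are merged before any
length is measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cgi_detect import CpGIsland
from .genome_io import (
    GenomicInterval,
    SequenceRecord,
    check_bounds,
    coverage,
    genome_lengths,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)


@dataclass(frozen=True)
class DivergenceStats:
    """Genome-level similar/divergent length bookkeeping.

    The divergent length is the complement of the merged similar coverage;
    the proportion is divergent over total.
    """

    total_len: int
    divergent_len: int

    @property
    def similar_len(self) -> int:
        return self.total_len - self.divergent_len

    @property
    def proportion(self) -> float:
        return self.divergent_len / self.total_len

    def proportion_percent(self, decimals: int = 3) -> float:
        """Proportion in percent, rounded for reporting (e.g. 5.751)."""
        return round(100.0 * self.proportion, decimals)

    @classmethod
    def from_lengths(cls, total_len: int, divergent_len: int) -> "DivergenceStats":
        if not (0 <= divergent_len <= total_len):
            raise ValueError("need 0 <= divergent_len <= total_len")
        return cls(total_len=total_len, divergent_len=divergent_len)


def divergence_stats(
    genome: Iterable[SequenceRecord] | dict[str, int],
    similar: Sequence[GenomicInterval],
) -> DivergenceStats:
    """Divergent-length statistics from a genome and its similar regions."""
    lengths = genome if isinstance(genome, dict) else genome_lengths(genome)
    check_bounds(similar, lengths)
    total = sum(lengths.values())
    similar_len = coverage(similar)
    return DivergenceStats(total_len=total, divergent_len=total - similar_len)


def associate_islands(
    islands: Iterable[CpGIsland],
    regions: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> tuple[list[CpGIsland], list[CpGIsland]]:
    """Partition islands into (associated, not associated) with the regions.

    An island is associated when it overlaps any region by >= ``min_overlap``
    bp (default 1 bp). Intervals are half-open, so bookended islands do not
    associate.
    """
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    associated: list[CpGIsland] = []
    unassociated: list[CpGIsland] = []
    for isl in islands:
        ovl = 0
        for iv in by_chrom.get(isl.chrom, []):
            if iv.start >= isl.end:
                break
            ovl += max(0, min(isl.end, iv.end) - max(isl.start, iv.start))
            if ovl >= min_overlap:
                break
        (associated if ovl >= min_overlap else unassociated).append(isl)
    return associated, unassociated


@dataclass(frozen=True)
class OverlapPartition:
    """Base-coverage partition between two island sets A and B."""

    unique_a_len: int
    shared_len: int
    unique_b_len: int

    @property
    def total_a(self) -> int:
        return self.unique_a_len + self.shared_len

    @property
    def total_b(self) -> int:
        return self.unique_b_len + self.shared_len

    @property
    def ratio(self) -> float:
        """Total coverage of A over total coverage of B."""
        return self.total_a / self.total_b


def _as_intervals(items: Iterable) -> list[GenomicInterval]:
    out = []
    for it in items:
        if isinstance(it, GenomicInterval):
            out.append(it)
        else:
            out.append(GenomicInterval(it.chrom, it.start, it.end))
    return out


def overlap_partition(set_a: Iterable, set_b: Iterable) -> OverlapPartition:
    """Merged-coverage set algebra between two island (or interval) sets."""
    a = _as_intervals(set_a)
    b = _as_intervals(set_b)
    shared = coverage(intersect_intervals(a, b))
    unique_a = coverage(subtract_intervals(a, b))
    unique_b = coverage(subtract_intervals(b, a))
    return OverlapPartition(
        unique_a_len=unique_a, shared_len=shared, unique_b_len=unique_b
    )


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    ovl = a.overlaps(b)
    if ovl == 0:
        return 0.0
    return min(ovl / len(a), ovl / len(b))


def recovery_rate(
    truth: Sequence[GenomicInterval],
    predicted: Iterable,
    min_reciprocal: float = 0.8,
) -> float:
    """Fraction of truth intervals matched by a prediction.

    A truth interval counts as recovered when some predicted interval (or
    island) overlaps it reciprocally by >= ``min_reciprocal`` of both
    lengths. Returns 1.0 for an empty truth set.
    """
    if not truth:
        return 1.0
    preds = _as_intervals(predicted)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in preds:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hit = 0
    for t in truth:
        if any(
            reciprocal_overlap(t, p) >= min_reciprocal
            for p in by_chrom.get(t.chrom, [])
        ):
            hit += 1
    return hit / len(truth)
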