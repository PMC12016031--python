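"""Per-CpG WGBS call parsing, island aggregation, and level classification.

A methylation call carries a read depth and, when depth > 0, a methylation
ratio in [0, 1]. Sites and islands are classified into four levels:

* invalid       (-1): no reads mapped
* hyper         ( 1): ratio > 0.75
* hypo          ( 2): ratio < 0.1
* intermediate  ( 3): otherwise (0.1 and 0.75 inclusive)

The island-level ratio is the depth-weighted mean over the member CpG calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .cgi_detect import CpGIsland
from .errors import FormatError
from .genome_io import GenomicInterval, merge_intervals


class MethylationLevel(IntEnum):
    INVALID = -1
    HYPER = 1
    HYPO = 2
    INTERMEDIATE = 3


LEVEL_NAMES = {
    MethylationLevel.INVALID: "invalid",
    MethylationLevel.HYPER: "hyper",
    MethylationLevel.HYPO: "hypo",
    MethylationLevel.INTERMEDIATE: "intermediate",
}

HYPER_THRESHOLD = 0.75
HYPO_THRESHOLD = 0.1


@dataclass(frozen=True)
class MethylationCall:
    """One CpG site's WGBS evidence: depth and methylation ratio."""

    chrom: str
    pos: int
    reads: int
    ratio: float | None

    def __post_init__(self):
        if self.reads < 0:
            raise FormatError(f"negative read count at {self.chrom}:{self.pos}")
        if self.reads > 0:
            if self.ratio is None or not (0.0 <= self.ratio <= 1.0):
                raise FormatError(
                    f"methylation ratio {self.ratio!r} outside [0,1] at "
                    f"{self.chrom}:{self.pos}"
                )


def read_calls(path, dialect: str = "tsv") -> list[MethylationCall]:
    """Read per-CpG calls from a TSV file.

    dialect "tsv": columns chrom, pos (0-based), reads, ratio; ratio may be
    "." or empty when reads is 0. dialect "bedmethyl": the 9+2 ENCODE layout
    where column 10 is coverage and column 11 percent methylation (divided by
    100 here); the start column (0-based) is the site position.

    Duplicate (chrom, pos) rows are rejected.
    """
    if dialect not in ("tsv", "bedmethyl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[MethylationCall] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "tsv":
                    if len(fields) < 4:
                        raise FormatError("expected 4 columns", path, lineno)
                    chrom, pos = fields[0], int(fields[1])
                    reads = int(fields[2])
                    raw_ratio = fields[3]
                    ratio = None if raw_ratio in (".", "") else float(raw_ratio)
                else:
                    if len(fields) < 11:
                        raise FormatError("expected >= 11 bedMethyl columns", path, lineno)
                    chrom, pos = fields[0], int(fields[1])
                    reads = int(fields[9])
                    ratio = float(fields[10]) / 100.0
            except ValueError:
                raise FormatError("non-numeric field", path, lineno) from None
            if reads == 0:
                ratio = None
            key = (chrom, pos)
            if key in seen:
                raise FormatError(f"duplicate call at {chrom}:{pos}", path, lineno)
            seen.add(key)
            try:
                calls.append(MethylationCall(chrom, pos, reads, ratio))
            except FormatError as exc:
                raise FormatError(str(exc), path, lineno) from None
    return calls


def write_calls(calls: Iterable[MethylationCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            ratio = "." if c.ratio is None else f"{c.ratio:.6f}"
            fh.write(f"{c.chrom}\t{c.pos}\t{c.reads}\t{ratio}\n")


def classify_site(call: MethylationCall) -> MethylationLevel:
    """Four-way level of a single call; thresholds are strict inequalities."""
    if call.reads == 0:
        return MethylationLevel.INVALID
    if call.ratio > HYPER_THRESHOLD:
        return MethylationLevel.HYPER
    if call.ratio < HYPO_THRESHOLD:
        return MethylationLevel.HYPO
    return MethylationLevel.INTERMEDIATE


class CallIndex:
    """Per-chromosome position-sorted arrays for fast range queries."""

    def __init__(self, calls: Iterable[MethylationCall]):
        by_chrom: dict[str, list[MethylationCall]] = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(c)
        self._pos: dict[str, np.ndarray] = {}
        self._reads: dict[str, np.ndarray] = {}
        self._ratio: dict[str, np.ndarray] = {}
        for chrom, group in by_chrom.items():
            group.sort(key=lambda c: c.pos)
            self._pos[chrom] = np.array([c.pos for c in group], dtype=np.int64)
            self._reads[chrom] = np.array([c.reads for c in group], dtype=np.int64)
            self._ratio[chrom] = np.array(
                [c.ratio if c.ratio is not None else np.nan for c in group]
            )

    def in_range(self, chrom: str, start: int, end: int):
        """(reads, ratio) arrays for calls with start <= pos < end."""
        if chrom not in self._pos:
            return (np.empty(0, dtype=np.int64), np.empty(0))
        pos = self._pos[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return self._reads[chrom][lo:hi], self._ratio[chrom][lo:hi]

    def check_against_cpgs(self, chrom: str, cpg_starts: np.ndarray) -> int:
        """Warn about (and count) calls not matching a genome CpG position.

        Mismatches are kept, not dropped: a call at a non-CpG position is a
        reference/call mismatch worth surfacing.
        """
        if chrom not in self._pos:
            return 0
        mism = int(np.count_nonzero(~np.isin(self._pos[chrom], cpg_starts)))
        if mism:
            warnings.warn(
                f"{mism} methylation calls on {chrom} do not coincide with a "
                "reference CpG position",
                stacklevel=2,
            )
        return mism


def cgi_mean_methylation(
    island: CpGIsland, calls: CallIndex | Iterable[MethylationCall]
) -> float | None:
    """Depth-weighted mean methylation ratio of calls inside the island.

    Returns None (invalid) when no call overlaps the island or every
    overlapping call has zero reads.
    """
    index = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    reads, ratio = index.in_range(island.chrom, island.start, island.end)
    total = int(reads.sum())
    if total == 0:
        return None
    covered = reads > 0
    return float(np.sum(reads[covered] * ratio[covered]) / total)


def classify_cgi(
    island: CpGIsland, calls: CallIndex | Iterable[MethylationCall]
) -> MethylationLevel:
    """Classify an island by its depth-weighted mean ratio."""
    mean = cgi_mean_methylation(island, calls)
    if mean is None:
        return MethylationLevel.INVALID
    if mean > HYPER_THRESHOLD:
        return MethylationLevel.HYPER
    if mean < HYPO_THRESHOLD:
        return MethylationLevel.HYPO
    return MethylationLevel.INTERMEDIATE


@dataclass(frozen=True)
class LevelTally:
    """Counts and proportions per methylation level (invalid included)."""

    counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict | None:
        """Per-level fractions over all entities; None for an empty tally."""
        n = self.total
        if n == 0:
            return None
        return {lvl: c / n for lvl, c in self.counts.items()}


def _entity_interval(entity) -> GenomicInterval:
    if isinstance(entity, MethylationCall):
        return GenomicInterval(entity.chrom, entity.pos, entity.pos + 1)
    return GenomicInterval(entity.chrom, entity.start, entity.end)


def tally_levels(
    entities,
    regions: Sequence[GenomicInterval] | None = None,
) -> LevelTally:
    """Tally levels over classified entities.

    ``entities`` is an iterable of (entity, level) pairs — entity a
    :class:`MethylationCall` or :class:`CpGIsland` — or of bare levels when
    no region restriction is requested. With ``regions``, only entities
    overlapping the merged regions by >= 1 bp are counted.
    """
    counts = {lvl: 0 for lvl in MethylationLevel}
    if regions is not None:
        merged = merge_intervals(regions)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    for item in entities:
        if isinstance(item, tuple):
            entity, level = item
        else:
            entity, level = None, item
        if regions is not None:
            if entity is None:
                raise ValueError("region restriction requires (entity, level) pairs")
            iv = _entity_interval(entity)
            if not any(iv.overlaps(r) for r in by_chrom.get(iv.chrom, [])):
                continue
        counts[MethylationLevel(level)] += 1
    return LevelTally(counts=counts)
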