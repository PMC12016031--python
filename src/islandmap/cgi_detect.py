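"""CpG island prediction under two formal definitions.

Density-defined islands follow the classical Gardiner-Garden & Frommer rule
(length >= 200 bp, GC content >= 50%, observed/expected CpG ratio >= 0.6)
found by a CpGPlot-style sliding-window scan: qualifying windows are merged,
each merged run is trimmed to begin and end on a CG dinucleotide, and the
thresholds are re-verified on the final coordinates.

Position-defined islands follow the CpGcluster idea: CpG start coordinates
are segmented into maximal runs whose neighbor distances

    d_i = x_{i+1} - x_i - 1

are all <= d_max, and a run is kept when its probability under a geometric
null — P(d) = (1-p)^(d-1) * p with p the genome-wide per-position CpG
frequency — is small. The cluster P value is the product of the per-gap
geometric probabilities, computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedContentError, UndefinedRatioError
from .cpg_context import cpg_positions
from .genome_io import SequenceRecord

DEFAULT_D_VALUES = (12, 25, 50)
DEFAULT_ALPHA = 1e-5


@dataclass(frozen=True)
class CpGIsland:
    """A predicted CpG island with its summary features.

    ``method`` is "density" or "position"; ``d_param`` is set for the
    position method only; ``p_value`` for the position method only.
    ``cpg_density`` is in CpGs per 100 bp.
    """

    chrom: str
    start: int
    end: int
    method: str
    d_param: int | None = None
    n_cpg: int | None = None
    gc_content: float | None = None
    oe_ratio: float | None = None
    cpg_density: float | None = None
    p_value: float | None = None

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        if self.method == "position":
            return f"position:d{self.d_param}"
        return self.method


@dataclass(frozen=True)
class DistanceModel:
    """Geometric null for CpG spacing: per-position CpG start probability."""

    p: float
    source_length: int
    source_cpg_count: int

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"CpG probability p={self.p} outside (0,1)")

    @classmethod
    def from_record(cls, record: SequenceRecord) -> "DistanceModel":
        """Estimate p as (#CpG) / (non-N length) of the chromosome."""
        length = sum(1 for b in record.sequence if b != "N")
        n_cpg = len(cpg_positions(record))
        return cls(p=n_cpg / length, source_length=length, source_cpg_count=n_cpg)


# ---------------------------------------------------------------------------
# Composition features


def _counts(seq: str) -> tuple[int, int, int, int]:
    """(#C, #G, #CpG, non-N length)."""
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_c = int(np.count_nonzero(b == ord("C")))
    n_g = int(np.count_nonzero(b == ord("G")))
    n_n = int(np.count_nonzero(b == ord("N")))
    n_cpg = int(np.count_nonzero((b[:-1] == ord("C")) & (b[1:] == ord("G")))) if len(b) > 1 else 0
    return n_c, n_g, n_cpg, len(b) - n_n


def gc_content(seq: str | SequenceRecord) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both sides."""
    s = seq if isinstance(seq, str) else seq.sequence
    if not s:
        raise UndefinedContentError("empty sequence")
    n_c, n_g, _, n_valid = _counts(s)
    if n_valid == 0:
        raise UndefinedContentError("sequence is all N; GC content undefined")
    return (n_c + n_g) / n_valid


def oe_ratio(seq: str | SequenceRecord) -> float:
    """Observed/expected CpG ratio: (#CpG * L) / (#C * #G), L = non-N length.

    Returns a defined 0.0 when the sequence has C and G but no CpG; raises
    when #C or #G is zero (the expectation is then degenerate).
    """
    s = seq if isinstance(seq, str) else seq.sequence
    if not s:
        raise UndefinedRatioError("empty sequence")
    n_c, n_g, n_cpg, n_valid = _counts(s)
    if n_c == 0 or n_g == 0:
        raise UndefinedRatioError(
            f"O/E undefined: #C={n_c}, #G={n_g} (expected CpG count is zero)"
        )
    if n_cpg == 0:
        return 0.0
    return n_cpg * n_valid / (n_c * n_g)


def island_features(island: CpGIsland, record: SequenceRecord) -> CpGIsland:
    """Return a copy of the island with its summary features populated."""
    if island.end > len(record) or island.chrom != record.name:
        raise ValueError(f"island {island.chrom}:{island.start}-{island.end} outside record")
    sub = record.sequence[island.start : island.end]
    n_cpg = len(cpg_positions(sub))
    length = len(sub)
    return replace(
        island,
        n_cpg=n_cpg,
        gc_content=gc_content(sub),
        oe_ratio=oe_ratio(sub),
        cpg_density=n_cpg / length * 100.0,
    )


# ---------------------------------------------------------------------------
# Density-defined islands


def predict_density_cgis(
    record: SequenceRecord,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 100,
    step: int = 1,
) -> list[CpGIsland]:
    """Sliding-window prediction of density-defined islands.

    Windows of ``window`` bp advanced by ``step`` are marked when their GC
    content and O/E ratio meet the thresholds; windows containing N are
    disqualified. Following the CpGPlot convention, a marked window asserts
    island-ness at its midpoint: runs of adjacent marked midpoints merge
    into candidate regions, each region's edges are snapped to the nearest
    CG dinucleotide so islands begin and end on a CpG, and a region is kept
    only if its final length is >= ``min_len`` and the whole-region GC and
    O/E still meet the thresholds. Midpoint (rather than full-span)
    assignment keeps island boundaries from bleeding into flanking sequence
    that merely shares a window with the island proper.
    """
    if window > min_len:
        raise ValueError(f"window ({window}) must not exceed min_len ({min_len})")
    seq = record.sequence
    L = len(seq)
    if L < window:
        return []

    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (b == ord("C")).astype(np.int64)
    is_g = (b == ord("G")).astype(np.int64)
    is_n = (b == ord("N")).astype(np.int64)
    cg = np.zeros(L, dtype=np.int64)
    cg[: L - 1] = (b[:-1] == ord("C")) & (b[1:] == ord("G"))

    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_n = np.concatenate(([0], np.cumsum(is_n)))
    cum_cg = np.concatenate(([0], np.cumsum(cg)))

    starts = np.arange(0, L - window + 1, step)
    wc = cum_c[starts + window] - cum_c[starts]
    wg = cum_g[starts + window] - cum_g[starts]
    wn = cum_n[starts + window] - cum_n[starts]
    # CpG dinucleotides fully inside the window: starts in [s, s+window-1)
    wcg = cum_cg[starts + window - 1] - cum_cg[starts]

    gc_ok = (wc + wg) >= min_gc * window
    with np.errstate(divide="ignore", invalid="ignore"):
        # O/E >= threshold <=> cpg * L >= threshold * C * G (C,G > 0)
        oe_ok = (wcg * window) >= (min_oe * wc * wg)
    oe_ok &= (wc > 0) & (wg > 0)
    marked = gc_ok & oe_ok & (wn == 0)

    idx = np.nonzero(marked)[0]
    if len(idx) == 0:
        return []
    marked_starts = starts[idx]

    cpg_all = cpg_positions(seq)
    if len(cpg_all) == 0:
        return []
    half = window // 2
    islands: list[CpGIsland] = []
    run_start = prev = marked_starts[0]
    runs: list[tuple[int, int]] = []
    for s in marked_starts[1:]:
        if s - prev <= step:  # adjacent marked midpoints continue the run
            prev = s
        else:
            runs.append((run_start + half, prev + half + 1))
            run_start = prev = s
    runs.append((run_start + half, prev + half + 1))

    def nearest_cpg(target: int) -> int:
        k = int(np.searchsorted(cpg_all, target))
        best = max(0, min(k, len(cpg_all) - 1))
        if k > 0 and abs(cpg_all[k - 1] - target) <= abs(cpg_all[best] - target):
            best = k - 1
        return best

    for rs, re_ in runs:
        # snap edges to CG dinucleotides: first CG nearest the run start,
        # last CG whose end is nearest the run end
        lo = nearest_cpg(rs)
        hi = nearest_cpg(re_ - 2)
        if hi < lo:
            continue
        start, end = int(cpg_all[lo]), int(cpg_all[hi]) + 2
        if end - start < min_len:
            continue
        sub = seq[start:end]
        try:
            if gc_content(sub) < min_gc or oe_ratio(sub) < min_oe:
                continue
        except (UndefinedContentError, UndefinedRatioError):
            continue
        islands.append(
            island_features(CpGIsland(record.name, start, end, "density"), record)
        )
    return islands


# ---------------------------------------------------------------------------
# Position-defined islands


def inter_cpg_distances(positions: Sequence[int] | np.ndarray) -> np.ndarray:
    """Neighbor distances d_i = x_{i+1} - x_i - 1 (empty for < 2 positions)."""
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) < 2:
        return np.empty(0, dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("CpG positions must be strictly increasing")
    return np.diff(pos) - 1


def geometric_prob(d: int, model: DistanceModel) -> float:
    """P(d) = (1-p)^(d-1) * p for a neighbor distance d >= 1."""
    if d < 1:
        raise ValueError(f"distance d={d} out of domain (d >= 1)")
    return (1.0 - model.p) ** (d - 1) * model.p


def cluster_cpgs(
    positions: Sequence[int] | np.ndarray, d_max: int
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive CpGs with all neighbor distances <= d_max.

    Returns half-open index ranges (i, j) into ``positions``; runs with fewer
    than 2 CpGs are discarded.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) < 2:
        return []
    d = inter_cpg_distances(pos)
    breaks = np.nonzero(d > d_max)[0]
    bounds = np.concatenate(([0], breaks + 1, [len(pos)]))
    return [
        (int(bounds[k]), int(bounds[k + 1]))
        for k in range(len(bounds) - 1)
        if bounds[k + 1] - bounds[k] >= 2
    ]


def cluster_log_pvalue(
    cluster_positions: Sequence[int] | np.ndarray, model: DistanceModel
) -> float:
    """Natural-log P value of a cluster under the geometric null.

    The cluster P value is the product over intra-cluster distances of
    P(d_i); the log form avoids underflow for long clusters.
    """
    d = inter_cpg_distances(cluster_positions)
    if len(d) == 0:
        raise ValueError("cluster needs >= 2 CpGs")
    return float(np.sum((d - 1) * math.log1p(-model.p) + math.log(model.p)))


def cluster_pvalue(
    cluster_positions: Sequence[int] | np.ndarray, model: DistanceModel
) -> float:
    """Product of per-gap geometric probabilities (may underflow to 0.0)."""
    return math.exp(cluster_log_pvalue(cluster_positions, model))


def predict_position_cgis(
    record: SequenceRecord,
    d_max: int,
    alpha: float = DEFAULT_ALPHA,
    model: DistanceModel | None = None,
) -> list[CpGIsland]:
    """Distance-clustering prediction of position-defined islands.

    The geometric null is estimated chromosome-wise unless ``model`` is
    given. Clusters with P value < alpha become islands spanning the first
    member CpG's start to the last member's start + 2.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    pos = cpg_positions(record)
    if len(pos) < 2:
        return []
    if model is None:
        model = DistanceModel.from_record(record)
    log_alpha = math.log(alpha)
    islands: list[CpGIsland] = []
    for i, j in cluster_cpgs(pos, d_max):
        members = pos[i:j]
        logp = cluster_log_pvalue(members, model)
        # alpha = 1 disables the filter entirely (log P <= 0 always)
        if alpha < 1.0 and not (logp < log_alpha):
            continue
        isl = CpGIsland(
            record.name,
            int(members[0]),
            int(members[-1]) + 2,
            "position",
            d_param=d_max,
            p_value=math.exp(logp),
        )
        islands.append(island_features(isl, record))
    return islands
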