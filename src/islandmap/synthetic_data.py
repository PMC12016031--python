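"""Seeded synthetic genomes, planted islands, and synthetic WGBS calls.

The generator emulates the inputs of a comparative CGI/methylation study at
desk scale: an AT-rich background with depleted CpG dinucleotides (mammalian
genomes carry roughly a quarter of the CpGs expected from composition),
planted CpG-dense GC-rich islands that satisfy both island definitions,
"divergent" intervals standing in for regions without a qualifying
whole-genome alignment, and per-CpG methylation calls with Poisson-like
coverage, a three-component (hyper/hypo/intermediate) ratio mixture, and a
configurable fraction of zero-coverage sites.

Every draw comes from one numpy Generator seeded from the config, so equal
seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cpg_context import cpg_positions
from .errors import ConfigError
from .genome_io import GenomicInterval, SequenceRecord, write_bed, write_fasta
from .methylation import MethylationCall, MethylationLevel, write_calls

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and methylation calls.

    Defaults: a 40% GC background with CpGs depleted to a quarter of the
    compositional expectation; 10 planted islands per chromosome, 250-1000 bp
    long, GC-rich, with per-position CpG start probability 0.12 (mean
    neighbor spacing well under the tightest clustering threshold);
    5% of each chromosome marked divergent; WGBS coverage with mean 30 reads
    and 10% unmapped (invalid) sites; site-level mixture 30% hyper, 50% hypo,
    20% intermediate, with hypo-methylation boosted threefold inside islands.
    """

    n_chroms: int = 2
    chrom_length: int = 200_000
    background_gc: float = 0.40
    background_cpg_depletion: float = 0.25
    n_islands: int = 10
    island_length: tuple[int, int] = (250, 1000)
    island_cpg_prob: float = 0.12
    island_gc: float = 0.60
    divergent_fraction: float = 0.05
    n_divergent: int = 5
    coverage_mean: float = 30.0
    level_weights: tuple[float, float, float] = (0.3, 0.5, 0.2)  # hyper, hypo, inter
    invalid_rate: float = 0.1
    island_hypo_boost: float = 3.0
    seed: int = 42

    def validate(self) -> None:
        fracs = {
            "background_gc": self.background_gc,
            "background_cpg_depletion": self.background_cpg_depletion,
            "island_cpg_prob": self.island_cpg_prob,
            "island_gc": self.island_gc,
            "divergent_fraction": self.divergent_fraction,
            "invalid_rate": self.invalid_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0,1]")
        if abs(sum(self.level_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.level_weights
        ):
            raise ConfigError("level_weights must be non-negative and sum to 1")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ConfigError("need n_chroms >= 1 and chrom_length >= 1")
        lo, hi = self.island_length
        if not (0 < lo <= hi):
            raise ConfigError("island_length range must be positive and ordered")
        if self.coverage_mean < 1:
            raise ConfigError("coverage_mean must be >= 1")


@dataclass
class TruthSet:
    """Ground truth written alongside the synthetic data."""

    islands: list[GenomicInterval] = field(default_factory=list)
    divergent: list[GenomicInterval] = field(default_factory=list)
    site_levels: dict = field(default_factory=dict)  # (chrom, pos) -> level


# ---------------------------------------------------------------------------
# Genome generation

# Margin kept between planted islands (and chromosome ends) so that island
# recovery is unambiguous and the flanks look like plain background.
ISLAND_GAP = 1000


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=probs)]


def _deplete_cpgs(
    rng: np.random.Generator, seq: np.ndarray, keep_fraction: float
) -> None:
    """Break up excess CG pairs in place.

    One base of each doomed pair (C or G, coin flip) is replaced by A or T;
    neither replacement can form a new CpG with a neighboring base, so the
    depletion factor is honored exactly on the existing pairs. The genome GC
    fraction dips slightly below nominal (~3 points at default settings),
    mimicking the AT bias around depleted CpGs in real genomes.
    """
    cg = np.nonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))[0]
    doomed = cg[rng.random(len(cg)) >= keep_fraction]
    side = rng.integers(0, 2, size=len(doomed))  # 0: replace C, 1: replace G
    repl = np.where(rng.integers(0, 2, size=len(doomed)) == 0, ord("A"), ord("T"))
    seq[doomed + side] = repl


def _island_sequence(
    rng: np.random.Generator, length: int, cpg_prob: float, gc: float
) -> np.ndarray:
    """A CpG-dense GC-rich island body.

    At each position a CG dinucleotide is emitted with probability
    ``cpg_prob``, otherwise a single base from a GC-rich composition. A CG is
    forced whenever 20 bp have passed since the last one, so the neighbor
    distances stay below every clustering threshold in routine use, and the
    body begins and ends on a CG.
    """
    # non-CpG filler composition chosen so overall GC lands above `gc`
    filler_gc = max(0.0, (gc - 0.24) / 0.79)
    filler_gc = min(1.0, filler_gc + 0.1)
    probs = np.array(
        [(1 - filler_gc) / 2, filler_gc / 2, filler_gc / 2, (1 - filler_gc) / 2]
    )
    out = np.empty(length, dtype=np.uint8)
    i = 0
    since_cg = 99  # force a CG at the very start
    while i < length:
        if i + 1 < length and (since_cg >= 19 or rng.random() < cpg_prob):
            out[i], out[i + 1] = ord("C"), ord("G")
            i += 2
            since_cg = 0
        else:
            out[i] = _BASES[rng.choice(4, p=probs)]
            i += 1
            since_cg += 1
    # end on a CG so the planted interval is flush with its member CpGs
    if length >= 2:
        out[length - 2], out[length - 1] = ord("C"), ord("G")
    return out


def _place_intervals(
    rng: np.random.Generator, chrom_length: int, lengths: list[int], gap: int
) -> list[tuple[int, int]]:
    """Place intervals left-to-right with >= gap separation, jittered."""
    n = len(lengths)
    if n == 0:
        return []
    needed = sum(lengths) + gap * (n + 1)
    if needed > chrom_length:
        raise ConfigError(
            f"cannot place {n} islands of total length {sum(lengths)} with "
            f"{gap} bp gaps on a {chrom_length} bp chromosome"
        )
    slack = chrom_length - needed
    # split the slack randomly among the n+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    extra = np.diff(np.concatenate(([0], cuts)))
    placed = []
    pos = gap
    for k, L in enumerate(lengths):
        pos += int(extra[k])
        placed.append((pos, pos + L))
        pos += L + gap
    return placed


def generate_genome(config: SimulationConfig) -> tuple[list[SequenceRecord], TruthSet]:
    """Generate the synthetic genome and its truth intervals."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    truth = TruthSet()
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq = _random_background(rng, config.chrom_length, config.background_gc)
        _deplete_cpgs(rng, seq, config.background_cpg_depletion)

        lo, hi = config.island_length
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_islands)]
        for start, end in _place_intervals(
            rng, config.chrom_length, lengths, ISLAND_GAP
        ):
            seq[start:end] = _island_sequence(
                rng, end - start, config.island_cpg_prob, config.island_gc
            )
            truth.islands.append(GenomicInterval(chrom, start, end, "island"))

        div_total = int(round(config.divergent_fraction * config.chrom_length))
        if div_total > 0:
            n_div = min(config.n_divergent, div_total)
            base = div_total // n_div
            div_lengths = [base] * n_div
            div_lengths[-1] += div_total - base * n_div
            for start, end in _place_intervals(
                rng, config.chrom_length, div_lengths, gap=0
            ):
                truth.divergent.append(GenomicInterval(chrom, start, end, "divergent"))

        records.append(SequenceRecord(chrom, seq.tobytes().decode("ascii")))
    return records, truth


# ---------------------------------------------------------------------------
# Methylation call generation

# Ratio components stay strictly inside the classification bands so the
# generated truth labels are unambiguous under the strict thresholds.
_RATIO_RANGES = {
    MethylationLevel.HYPER: (0.7501, 1.0),
    MethylationLevel.HYPO: (0.0, 0.0999),
    MethylationLevel.INTERMEDIATE: (0.1001, 0.7499),
}
_LEVELS = (
    MethylationLevel.HYPER,
    MethylationLevel.HYPO,
    MethylationLevel.INTERMEDIATE,
)


def generate_methylation(
    records: list[SequenceRecord], truth: TruthSet, config: SimulationConfig
) -> list[MethylationCall]:
    """Simulate per-CpG calls on every plus-strand CpG of the genome.

    Coverage is 1 + Poisson(coverage_mean - 1) so mapped sites always have
    at least one read; the true level of each site is drawn from the
    configured mixture, with the hypo component multiplied by
    ``island_hypo_boost`` (then renormalized) inside planted islands. The
    drawn truth labels are recorded in ``truth.site_levels``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    weights = np.asarray(config.level_weights, dtype=float)
    w_island = weights * np.array([1.0, config.island_hypo_boost, 1.0])
    w_island /= w_island.sum()

    island_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in truth.islands:
        island_by_chrom.setdefault(iv.chrom, []).append(iv)

    calls: list[MethylationCall] = []
    for rec in records:
        ivs = sorted(island_by_chrom.get(rec.name, []))
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        for pos in cpg_positions(rec):
            pos = int(pos)
            if rng.random() < config.invalid_rate:
                truth.site_levels[(rec.name, pos)] = MethylationLevel.INVALID
                calls.append(MethylationCall(rec.name, pos, 0, None))
                continue
            k = np.searchsorted(starts, pos, side="right") - 1
            in_island = k >= 0 and pos < ends[k]
            w = w_island if in_island else weights
            level = _LEVELS[rng.choice(3, p=w)]
            lo, hi = _RATIO_RANGES[level]
            ratio = float(rng.uniform(lo, hi))
            reads = 1 + int(rng.poisson(config.coverage_mean - 1.0))
            truth.site_levels[(rec.name, pos)] = level
            calls.append(MethylationCall(rec.name, pos, reads, ratio))
    return calls


# ---------------------------------------------------------------------------
# Bundle writer


def write_truth_levels(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), level in sorted(truth.site_levels.items()):
            fh.write(f"{chrom}\t{pos}\t{int(level)}\n")


def simulate_bundle(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run the full simulation and write FASTA, truth BEDs, and call TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_genome(config)
    calls = generate_methylation(records, truth, config)
    paths = {
        "genome": outdir / "genome.fasta",
        "islands": outdir / "true_islands.bed",
        "divergent": outdir / "divergent.bed",
        "calls": outdir / "calls.tsv",
        "truth_levels": outdir / "truth_levels.tsv",
    }
    write_fasta(records, paths["genome"])
    write_bed(sorted(truth.islands), paths["islands"])
    write_bed(sorted(truth.divergent), paths["divergent"])
    write_calls(calls, paths["calls"])
    write_truth_levels(truth, paths["truth_levels"])
    return paths
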