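"""End-to-end orchestration: context counts -> islands -> regions -> methylation.

The pipeline is deterministic given its config and inputs: no stage samples,
and every report is written with explicit sorting and rounding, so re-running
a config produces byte-identical output files.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cgi_detect import (
    DEFAULT_ALPHA,
    DEFAULT_D_VALUES,
    CpGIsland,
    predict_density_cgis,
    predict_position_cgis,
)
from .cpg_context import count_contexts
from .errors import ConfigError, IslandmapError
from .genome_io import (
    GenomicInterval,
    SequenceRecord,
    complement_regions,
    read_bed,
    read_fasta,
    write_bed,
)
from .methylation import (
    LEVEL_NAMES,
    CallIndex,
    MethylationLevel,
    classify_cgi,
    classify_site,
    read_calls,
    tally_levels,
)
from .region_compare import associate_islands, divergence_stats, overlap_partition


class StageError(IslandmapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (YAML-backed).

    ``genomes`` maps a genome label to its FASTA path; ``similar`` optionally
    maps the same labels to BED/TSV files of similar (aligned) regions;
    ``calls`` maps a tissue label to either one call file (single genome) or
    a per-genome mapping.
    """

    genomes: dict[str, str]
    similar: dict[str, str] = field(default_factory=dict)
    calls: dict[str, dict[str, str]] = field(default_factory=dict)
    min_len: int = 200
    min_gc: float = 0.5
    min_oe: float = 0.6
    window: int = 100
    d_values: tuple[int, ...] = DEFAULT_D_VALUES
    alpha: float = DEFAULT_ALPHA
    calls_dialect: str = "tsv"
    association_min_overlap: int = 1
    outdir: str = "islandmap_out"
    seed: int = 0

    def __post_init__(self):
        if not self.genomes:
            raise ConfigError("at least one genome is required")
        if not self.d_values:
            raise ConfigError("d_values must be non-empty")
        if not (0 < self.min_gc <= 1 and self.min_oe >= 0 and self.min_len > 0):
            raise ConfigError("invalid density thresholds")
        if not (0 < self.alpha <= 1):
            raise ConfigError("alpha outside (0, 1]")
        # normalize single-genome call shorthand {tissue: path}
        norm: dict[str, dict[str, str]] = {}
        for tissue, spec in self.calls.items():
            if isinstance(spec, dict):
                norm[tissue] = dict(spec)
            else:
                norm[tissue] = {g: spec for g in self.genomes}
        self.calls = norm

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"pipeline config {path} is not a mapping")
        if "d_values" in raw:
            raw["d_values"] = tuple(raw["d_values"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config key: {exc}") from None


def summarize_cgi_stats(
    islands_by_key: dict[tuple[str, int | None], list[CpGIsland]],
) -> pd.DataFrame:
    """Per (method, d): island count and mean length (rounded to integer bp).

    Mean length of an empty set is reported as NA.
    """
    rows = []
    for (method, d), islands in islands_by_key.items():
        n = len(islands)
        mean_len = round(sum(len(i) for i in islands) / n) if n else pd.NA
        rows.append({"method": method, "d": d if d is not None else pd.NA,
                     "count": n, "mean_length": mean_len})
    return pd.DataFrame(rows, columns=["method", "d", "count", "mean_length"])


def _features_frame(islands: list[CpGIsland]) -> pd.DataFrame:
    rows = [
        {
            "island_id": f"{isl.chrom}:{isl.start}-{isl.end}",
            "chrom": isl.chrom,
            "start": isl.start,
            "end": isl.end,
            "length": len(isl),
            "n_cpg": isl.n_cpg,
            "gc_content": round(isl.gc_content, 6),
            "oe_ratio": round(isl.oe_ratio, 6),
            "cpg_density_per_100bp": round(isl.cpg_density, 6),
            "p_value": "" if isl.p_value is None else f"{isl.p_value:.6e}",
        }
        for isl in islands
    ]
    cols = ["island_id", "chrom", "start", "end", "length", "n_cpg",
            "gc_content", "oe_ratio", "cpg_density_per_100bp", "p_value"]
    return pd.DataFrame(rows, columns=cols)


def _islands_to_bed(islands: list[CpGIsland], path) -> None:
    """BED6+: score is min(1000, 10 * -log10 P) for position islands, else 0."""
    with open(path, "w") as fh:
        for isl in sorted(islands, key=lambda i: (i.chrom, i.start, i.end)):
            if isl.p_value is None:
                score = 0
            elif isl.p_value <= 0.0:  # log-space underflow: saturate
                score = 1000
            else:
                score = min(1000, int(-10 * math.log10(isl.p_value)))
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.name}\t{score}\t.\n"
            )


def _tally_frame(tally, scope: str) -> list[dict]:
    rows = []
    props = tally.proportions
    for lvl in MethylationLevel:
        rows.append(
            {
                "scope": scope,
                "level": LEVEL_NAMES[lvl],
                "count": tally.counts[lvl],
                "percent": "" if props is None else f"{100 * props[lvl]:.2f}",
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns {output name: path}.

    Stages: context counts, density islands, position islands per d, feature
    tables, divergence stats and island association (when similar regions are
    given), the density-vs-position overlap partition, and methylation
    classification and tallies per tissue (when calls are given). A stage
    failure aborts the run with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log_lines: list[str] = [
        f"islandmap {__version__}",
        f"config: genomes={sorted(config.genomes)} d_values={list(config.d_values)} "
        f"alpha={config.alpha} min_len={config.min_len} min_gc={config.min_gc} "
        f"min_oe={config.min_oe} window={config.window} seed={config.seed}",
    ]
    skipped: list[str] = []

    def out(name: str, path: Path):
        outputs[name] = path
        return path

    def log(msg: str):
        log_lines.append(msg)
        print(f"[islandmap] {msg}", file=sys.stderr)

    for g_label in sorted(config.genomes):
        try:
            genome = read_fasta(config.genomes[g_label])
        except Exception as exc:
            raise StageError(f"read_genome:{g_label}", exc) from exc
        log(f"{g_label}: {len(genome)} sequences, {sum(len(r) for r in genome)} bp")

        # --- C-site context counts
        try:
            ctx = count_contexts(genome)
            ctx.to_csv(out(f"{g_label}.context_counts",
                           outdir / f"{g_label}.context_counts.tsv"),
                       sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"context_counts:{g_label}", exc) from exc
        log(f"{g_label}: context counts written")

        # --- island prediction
        islands_by_key: dict[tuple[str, int | None], list[CpGIsland]] = {}
        try:
            dens: list[CpGIsland] = []
            for rec in genome:
                dens.extend(
                    predict_density_cgis(
                        rec,
                        min_len=config.min_len,
                        min_gc=config.min_gc,
                        min_oe=config.min_oe,
                        window=config.window,
                    )
                )
            islands_by_key[("density", None)] = dens
            _islands_to_bed(dens, out(f"{g_label}.cgi_density",
                                      outdir / f"{g_label}.cgi_density.bed"))
            _features_frame(dens).to_csv(
                out(f"{g_label}.cgi_density.features",
                    outdir / f"{g_label}.cgi_density.features.tsv"),
                sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"density_islands:{g_label}", exc) from exc
        log(f"{g_label}: {len(dens)} density-defined islands")

        try:
            for d in config.d_values:
                posl: list[CpGIsland] = []
                for rec in genome:
                    posl.extend(predict_position_cgis(rec, d, alpha=config.alpha))
                islands_by_key[("position", d)] = posl
                _islands_to_bed(
                    posl, out(f"{g_label}.cgi_position_d{d}",
                              outdir / f"{g_label}.cgi_position_d{d}.bed"))
                _features_frame(posl).to_csv(
                    out(f"{g_label}.cgi_position_d{d}.features",
                        outdir / f"{g_label}.cgi_position_d{d}.features.tsv"),
                    sep="\t", index=False)
                log(f"{g_label}: {len(posl)} position-defined islands (d={d})")
        except Exception as exc:
            raise StageError(f"position_islands:{g_label}", exc) from exc

        summarize_cgi_stats(islands_by_key).to_csv(
            out(f"{g_label}.cgi_summary", outdir / f"{g_label}.cgi_summary.tsv"),
            sep="\t", index=False)

        # --- divergence arithmetic + association
        divergent_regions: list[GenomicInterval] | None = None
        if g_label in config.similar:
            try:
                similar = read_bed(config.similar[g_label])
                stats = divergence_stats(genome, similar)
                divergent_regions = complement_regions(similar, genome)
                pd.DataFrame(
                    [{
                        "genome": g_label,
                        "total_length_bp": stats.total_len,
                        "divergent_length_bp": stats.divergent_len,
                        "divergent_proportion_percent":
                            f"{stats.proportion_percent(3):.3f}",
                        "similar_length_bp": stats.similar_len,
                    }]
                ).to_csv(out(f"{g_label}.divergence",
                             outdir / f"{g_label}.divergence.tsv"),
                         sep="\t", index=False)
                write_bed(divergent_regions,
                          out(f"{g_label}.divergent",
                              outdir / f"{g_label}.divergent.bed"))
                for (method, d), islands in sorted(islands_by_key.items(),
                                                   key=lambda kv: (kv[0][0], kv[0][1] or 0)):
                    assoc, _ = associate_islands(
                        islands, divergent_regions,
                        min_overlap=config.association_min_overlap)
                    tag = method if d is None else f"{method}_d{d}"
                    _islands_to_bed(
                        assoc,
                        out(f"{g_label}.{tag}.divergent_associated",
                            outdir / f"{g_label}.{tag}.divergent_associated.bed"))
                log(f"{g_label}: divergence {stats.proportion_percent(3):.3f}%")
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"divergence:{g_label}", exc) from exc
        else:
            skipped.append(f"divergence:{g_label} (no similar regions configured)")

        # --- overlap partition density vs position (d = 25 when available)
        try:
            d_ref = 25 if 25 in config.d_values else config.d_values[0]
            part = overlap_partition(
                islands_by_key[("density", None)], islands_by_key[("position", d_ref)])
            pd.DataFrame(
                [{
                    "genome": g_label,
                    "d": d_ref,
                    "unique_density_bp": part.unique_a_len,
                    "shared_bp": part.shared_len,
                    "unique_position_bp": part.unique_b_len,
                    "density_over_position_ratio":
                        "" if part.total_b == 0 else f"{part.ratio:.2f}",
                }]
            ).to_csv(out(f"{g_label}.overlap_partition",
                         outdir / f"{g_label}.overlap_partition.tsv"),
                     sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"overlap_partition:{g_label}", exc) from exc

        # --- methylation
        for tissue in sorted(config.calls):
            if g_label not in config.calls[tissue]:
                skipped.append(f"methylation:{g_label}:{tissue} (no calls configured)")
                continue
            try:
                calls = read_calls(config.calls[tissue][g_label],
                                   dialect=config.calls_dialect)
                index = CallIndex(calls)
                site_pairs = [(c, classify_site(c)) for c in calls]
                with open(out(f"{g_label}.{tissue}.site_levels",
                              outdir / f"{g_label}.{tissue}.site_levels.tsv"),
                          "w") as fh:
                    fh.write("chrom\tpos\treads\tlevel_code\tlevel\n")
                    for c, lvl in sorted(site_pairs,
                                         key=lambda p: (p[0].chrom, p[0].pos)):
                        fh.write(f"{c.chrom}\t{c.pos}\t{c.reads}\t{int(lvl)}\t"
                                 f"{LEVEL_NAMES[lvl]}\n")

                rows = _tally_frame(tally_levels(lvl for _, lvl in site_pairs),
                                    "whole_genome")
                if divergent_regions is not None:
                    rows += _tally_frame(
                        tally_levels(site_pairs, regions=divergent_regions),
                        "divergent")
                pd.DataFrame(rows).to_csv(
                    out(f"{g_label}.{tissue}.site_level_tally",
                        outdir / f"{g_label}.{tissue}.site_level_tally.tsv"),
                    sep="\t", index=False)

                cgi_rows = []
                for (method, d), islands in sorted(
                        islands_by_key.items(),
                        key=lambda kv: (kv[0][0], kv[0][1] or 0)):
                    tally = tally_levels(classify_cgi(isl, index) for isl in islands)
                    tag = method if d is None else f"{method}_d{d}"
                    for row in _tally_frame(tally, tag):
                        cgi_rows.append(row)
                pd.DataFrame(cgi_rows).rename(columns={"scope": "cgi_set"}).to_csv(
                    out(f"{g_label}.{tissue}.cgi_level_proportions",
                        outdir / f"{g_label}.{tissue}.cgi_level_proportions.tsv"),
                    sep="\t", index=False)
                log(f"{g_label}/{tissue}: {len(calls)} calls classified")
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"methylation:{g_label}:{tissue}", exc) from exc
        if not config.calls:
            skipped.append(f"methylation:{g_label} (no call files configured)")

    for s in skipped:
        log_lines.append(f"skipped: {s}")
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["run_log"] = log_path
    return outputs
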