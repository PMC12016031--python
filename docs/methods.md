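# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). The NUCmer
`show-coords` importer converts its 1-based inclusive reference spans at the
parser boundary; nothing downstream ever sees 1-based coordinates. Interval
sets are merged (overlapping **or exactly bookended** records coalesce)
before any length accounting, so every reported length is base coverage,
not a sum over records. N runs are not excluded from region algebra — the
complement of the similar regions is purely positional — and are instead
handled by the predictors (below).

## Cytosine contexts

Every C on the plus strand and every G on the plus strand (a C on the minus
strand) is a potential methylation site. The context comes from the two
bases downstream in the site's own 5'→3' direction: `CG*` → CpG, `CHG` →
CHG, `CHH` → CHH, with H ∈ {A, C, T}. A CpG needs only one downstream base;
CHG/CHH need two. Sites whose deciding window is truncated by the sequence
end or touches an N are labeled *ambiguous* and excluded from three-way
tallies — exclusion keeps the CHG/CHH definitions exact rather than guessing
at Ns. Because CG is palindromic, island mathematics uses plus-strand CG
start positions only; per-strand CpG counts are equal by construction and
asserted as a property test.

## Density-defined islands

Thresholds: length ≥ 200 bp, GC ≥ 0.5, O/E ≥ 0.6, all configurable. GC
content excludes N from numerator and denominator; O/E = #CpG × L / (#C ×
#G) with L the non-N length, defined as 0 when #CpG = 0 and undefined
(raised) when #C or #G is 0.

Mechanics follow the CpGPlot lineage: a 100 bp window slides 1 bp at a
time (prefix-sum vectorized); a window passes when its GC and O/E meet the
thresholds and it contains no N. A passing window asserts island-ness **at
its midpoint**; maximal runs of adjacent marked midpoints form candidate
regions, each region's edges snap to the nearest CG dinucleotide (so
islands begin and end on a CpG), and the three thresholds are re-verified
on the final coordinates before the island is emitted. Midpoint assignment
is deliberate: marking a window's full span lets an island annex ~½ window
of flanking background on each side whenever the flank shares a window
with genuinely island-grade sequence, which misplaces boundaries on short
islands; the midpoint rule keeps the boundary error near the window's
resolution limit. The emitted set is self-verifying — a test re-measures
every island on its final coordinates.

Windows narrower than the minimum island length are required
(`window ≤ min_len`); islands shorter than the window are therefore not
detectable, a known property of this scan family.

## Position-defined islands

Neighbor distances dᵢ = xᵢ₊₁ − xᵢ − 1 over plus-strand CG starts (minimum
possible value 1, for adjacent `CGCG`). Clusters are maximal runs with all
dᵢ ≤ d_max; runs of fewer than two CpGs are discarded. The null model is a
geometric spacing distribution P(d) = (1 − p)^(d−1) p with p estimated per
chromosome as #CpG / non-N length ("probability of CpGs in the sequence"
read as sequence-wide frequency). A cluster's P value is the product of
its per-gap probabilities — the aggregation is our choice; the source
method states only the per-distance form — computed in log space to avoid
underflow (long clusters can reach products below double-precision range;
the stored `p_value` may underflow to 0.0 and the BED score saturates).
Clusters with P < α become islands; α defaults to 10⁻⁵ and α = 1 disables
the filter (cluster passthrough), which the maximality and nesting
property tests rely on. Island coordinates run from the first member CG
start to the last member CG start + 2, covering the final dinucleotide.

d_max defaults cover 12, 25 and 50 bp — the clustering scales at which
short regulatory CpG clusters, the promoter-associated demarcation, and
the classical default operate.

## Methylation

Calls are (chrom, pos, reads, ratio) rows; bedMethyl 9+2 input divides the
percent column by 100. Zero-read sites carry no ratio. Classification is
strict per the published thresholds: reads = 0 → invalid; ratio > 0.75 →
hyper; ratio < 0.1 → hypo; otherwise intermediate — so exactly 0.75 and
0.1 are intermediate. Island aggregation is the depth-weighted mean
Σ reads·ratio / Σ reads over calls inside [start, end); an island with no
covered call is invalid. The weighted mean is invariant to splitting a
call's reads at the same ratio (weight additivity, tested). Calls at
positions that do not coincide with a reference CpG are kept and warned
about — a reference/call mismatch is diagnostic signal, not noise to drop.
Tallies count all four levels including invalid, and proportions are over
all entities; an optional region restriction keeps entities overlapping
the merged regions by ≥ 1 bp.

## Divergence arithmetic and island association

Similar regions (from an external whole-genome aligner; the alignment
itself is out of scope) are merged, their coverage subtracted from the
genome total, and the divergent proportion reported in percent to 3
decimals. An island is "divergent-associated" when it overlaps the merged
divergent regions by at least 1 bp (configurable); half-open bookends do
not associate. The two-set coverage partition reports unique-A, shared and
unique-B base coverage after merging within each set, plus the ratio
(A-total / B-total).

## Synthetic data

The generator emulates the study's inputs at desk scale. Defaults — the
fixed study conditions for all tests — are: 2 chromosomes × 200 kb;
background drawn i.i.d. at 40 % GC with CpG dinucleotides depleted to 25 %
of the compositional expectation; 10 planted islands per chromosome, each
250–1000 bp; 5 % of each chromosome marked divergent; WGBS coverage
1 + Poisson(29) (mean 30, minimum 1 read); 10 % of sites unmapped
(invalid); site-level mixture 30 % hyper / 50 % hypo / 20 % intermediate
with the hypo weight tripled inside islands (position-defined islands are
the most hypo-methylated class in real germline data, and the boost
reproduces that contrast).

Depletion breaks each doomed CG pair by replacing one of its bases with A
or T: this cannot create a new CpG with a neighbor (a composition-
preserving CG→GC swap can, e.g. CGG→GCG, and in an early version halved
the effective depletion), at the cost of a ~3-point dip in genome GC below
nominal — an acceptable echo of the AT bias around depleted CpGs in real
genomes. Island bodies emit a CG with probability 0.12 per position, force
a CG whenever 20 bp pass without one (so every internal neighbor distance
stays ≤ 21, below the tightest routine clustering threshold), start and
end on a CG, and fill remaining positions at ~55 % GC, landing island GC
near 0.65 and O/E near 1. One planted truth therefore serves both
predictors. Ratio components are drawn strictly inside the classification
bands (hyper ∈ (0.7501, 1], hypo ∈ [0, 0.0999), intermediate ∈ (0.1001,
0.7499)), so classifying the generated calls must reproduce the generated
labels with zero error — any mismatch is an implementation bug, and the
round-trip is asserted over ten seeds.

All draws come from one `numpy` Generator seeded from the config (the call
generator uses seed + 1 so genomes and methylation are independently
reproducible); equal seeds give byte-identical FASTA, BED and TSV output.

What the simulator does **not** emulate: chromatin-domain autocorrelation
of methylation, read-level bisulfite chemistry and conversion errors,
repeat structure, centromeric satellite composition, and realistic
island length/GC distributions. Passing the planted-recovery benchmarks
therefore demonstrates correctness of the predictors' mechanics on clean
signal, not calibrated sensitivity on real genomes, where island edges are
gradual and the published genome-scale island counts depend strongly on
the predictor dialect.

## Pipeline and reporting

Stages run in order: context counts → density islands → position islands
per d → summaries → divergence + association (when similar regions are
configured) → coverage partition (density vs position, d = 25 when
available) → per-tissue methylation classification and tallies. A stage
failure aborts with the stage name. Reports round explicitly: divergence
percent to 3 decimals, level percentages to 2, mean island length to
integer bp; the run log records versions and parameters but no
timestamps, so identical configs yield byte-identical bundles. Skipped
stages (no regions, no calls) are listed in the log.

## Problem sizes

Tests and the acceptance script run the full stack on the default
simulation conditions (ten seeds of 2 × 200 kb genomes, ~6000 CpG calls
per genome), which exercises every code path at a scale where the
reference oracles (per-base scans, exhaustive segmentation, direct
recomputation) stay exact and fast.
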