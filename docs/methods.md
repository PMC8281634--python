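# Methods

This note records the models, the defaults and why they hold, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## Synthetic cohorts

The generator produces the statistical structure the analysis relies on, not
biological sequence.  A genome is a set of chromosomes (default 6, lengths
evenly spaced 220→120 Mb, centromere at 40% of the length) with genes placed
uniformly; 200 genes per chromosome by default, the order of magnitude of
expressed genes on a real chromosome arm and enough loci for arm-level
segmentation.  A clone tree starts at a diploid "normal" root; each tumor
clone's branch carries one or more arm-level events drawn so that **each arm
is used at most once in the whole tree**.  (Drawing independently from
arm × {gain, loss} can put a gain and a loss of the same arm on one lineage;
they cancel to CN 2 and silently delete the event from the ground truth,
making the true topology unrecoverable in principle.  Excluding reuse keeps
the truth identifiable.)  Topology is either random attachment or a chain;
the pipeline driver defaults to a chain because the amplified state is
modeled as arising from the non-amplified one.

Expression counts are negative binomial with mean
`L_s · p_g · (CN/2)^β`: library size `L_s` uniform in 0.8–1.5 M reads
(matching ~1.2 M uniquely mapped reads per microdissected sample), relative
expression `p_g` lognormal(0, 1) normalized to sum to 1, dosage exponent
β = 1 (linear dosage, the minimal assumption the CNV inference needs), and
overdispersion 0.15 (variance = μ + 0.15 μ²), a typical bulk-RNA value.
Two optional effects model the amplified state: a `signature_fold` (default
3×) applied to a random 40-gene set in amplified samples, and a `her2_fold`
(default 6×, from the 3–8× range a focal HER2 amplification produces beyond
the arm-level gain) applied to a designated HER2 stand-in gene.  WGS bins
are Poisson(depth · CN/2) on a 100-kbp grid.

FISH cells draw integer signals from per-group pmfs on 0–10 signals/cell:
non-amplified mass concentrated at 1–3, amplified wide with ~77% of mass at
≥4, intermediate ducts an equal per-cell mixture of the two populations
(the mixture identity of every cell is kept as truth).  Control-probe
signals sit near 2.  These shapes reproduce the qualitative form of
published per-duct distributions; no numerical reference distributions
exist to calibrate against, which is the main respect in which passing
tests do not certify behavior on real images.  Real data would also add
FFPE section truncation artifacts, segmentation errors and batch effects,
none of which are modeled.

## FISH model

Reference pmfs pool all cells of the hand-picked reference ducts
(cell-weighted) with Laplace smoothing α = 1 over the 11 signal values, so
no likelihood is exactly zero.  The per-cell posterior uses an uninformative
prior (π = ½); ties are called non-amplified (the conservative direction).
Signals above 10 are clipped to 10, matching the reference support.

Duct densities are Gaussian KDEs evaluated on the fixed 101-point grid with
Silverman's bandwidth floored at 0.25 — integer-valued samples can have
zero IQR and near-zero variance, and the floor keeps the estimator defined;
below 5 cells the KDE is replaced by the smoothed pmf linearly interpolated
to the grid.  Densities are renormalized to unit trapezoidal integral.

Grouping is by total-variation distance on the grid to each reference
(references interpolated to the same grid), with relative margin
m = |d_no − d_amp| / (d_no + d_amp).  m < τ (default 0.15) is called
intermediate; otherwise the nearer reference wins.  The margin rule is this
package's operationalization of "ambiguous"; PCA scores of the duct-density
matrix are reported for QC but never drive the decision.  A duct equidistant
from both references (including the degenerate d_no = d_amp = 0 case) is
intermediate by definition.

## CNV inference

Expression path: counts → cpm → `log2((cpm+1)/(normal-mean cpm+1))`, genes
with zero counts in all normals dropped patient-wide, loci ordered by
transcription termination site.  Two centering steps anchor the neutral
state at zero.  First, each sample's locus-level median is subtracted.
Second — and this is the step that matters — after segmentation each
sample's segment means are shifted so the locus-weighted median segment
level is zero.  The reason the locus-level median is not enough: per-gene
log2 noise (sd ≈ 0.6 at dispersion 0.15) is comparable to the copy-number
signal (0.585 for CN 3), so with a third of the genome gained the locus
median already sits well off the neutral level, and whole neutral arms then
cross the loss cutoff.  Segment means average the noise away, so their
weighted median is a reliable neutral anchor.  The assumption bought is
that at least half of the profiled loci are copy-neutral — standard for
this kind of recentering and true of DCIS-like genomes.

Joint segmentation is an exact O(n²)-per-chromosome dynamic program over
segmentations shared by all of a patient's samples, minimizing total
within-segment squared error plus γ per breakpoint, with segments of at
least `min_seg` = 5 loci (a chromosome with fewer loci stays one segment).
The default penalty is BIC-style, γ = 2 · S · σ̂² · ln n with S samples,
n loci, and σ̂² a robust noise variance from the median squared first
difference (median(d²)/(2·0.4549)).  This scales the penalty to the noise
while staying below the cost reduction of a true arm-level jump at the
default study conditions; a fixed multiple of S alone would not.  γ is
exposed in every entry point.  Segment boundaries in bp are midpoints
between flanking loci, extended to the chromosome ends when lengths are
known, so a whole-arm call covers the whole arm.

State calling uses the cutoff ladder with strict inequalities; a mean
exactly at a cutoff takes the less extreme state (the inequalities do not
cover equality, so ties resolve conservatively).  The focal filter resets
non-neutral segments strictly shorter than 10 Mb to neutral, then merges
same-state neighbors with locus-weighted means; the combined step is
idempotent.  Arm reduction calls a gain (loss) when ≥50% of the arm's
length lies in gain/amplification (loss/deletion) segments; by tiling, both
directions cannot exceed 50% simultaneously.  Chromosome restriction
(chr1–15 by default where present) is configurable.

The noise consensus adds N(0, 1) and N(0.5, 1.5) to the raw counts
(negatives clipped to zero, no rounding), reruns the full pipeline on each,
and keeps an event iff the same (sample, arm, direction) appears in at
least 2 of the 3 runs.  Noise seeds are recorded in the report.

The WGS path is identical from the log2-ratio step onward.  The
cross-platform check assigns each gene its covering segment's mean log2 on
each platform and reports per-sample Spearman correlation over shared genes
(missing when fewer than 10).  The block view averages per-gene relative
expression (cpm ratio to the normal mean) within half-open 0.5-Mb windows
keyed by transcription termination site and reports log2 of the block mean;
gene-free blocks are missing, not zero.

## Phylogeny

Characters are binary presence of (arm, direction) events; constant-zero
columns are dropped.  The tree is rooted by an implicit all-zero normal
ancestor: scoring is Sankoff with unit costs and the root branch counted,
i.e. the score is min over root states of (subtree cost + [root ≠ normal]).
This makes "two samples sharing one event" cost 1, as it should.  The exact
mode enumerates all rooted leaf-labeled binary topologies ((2n−3)!!,
practical to 7 leaves).  The heuristic starts from neighbor joining on
Hamming distances with the normal root added as a pseudo-leaf (rooted at
its attachment), then hill-climbs over the subtree-prune-and-regraft
neighborhood; on score plateaus it explores up to 200 equal-score
topologies breadth-first before stopping, because parsimony landscapes are
full of flat ridges that defeat plain hill climbing.  Everything is
seed-free and deterministic: ties break on the canonical Newick string.
After state assignment (ties resolve toward the parent state), internal
branches carrying no change are collapsed, so identical samples form
polytomies and the output does not assert unsupported resolution.

AU support: average-linkage Euclidean dendrogram on the full matrix; for
each scale r in 0.5–1.4 (step 0.1), B bootstrap resamples of round(r·p)
feature columns; BP_r = fraction of resampled dendrograms containing the
cluster; least-squares fit of Φ⁻¹(1−BP_r) = v√r + c/√r over scales with
0 < BP_r < 1; AU = 1 − Φ(v−c).  Clusters with BP 0 or 1 at every usable
scale get AU 0 or 1 and a degenerate flag.  Columns are canonically sorted
before resampling, making the result exactly invariant to input column
order.  B = 1000 and the ten scales match common defaults and are
configurable.

Event statistics: a group's event set is those events in ≥2 of its samples;
shared / unique_amp / unique_noamp percentages are computed over the union
of the two groups' called events (event-level counting, not
event-sample-pair counting); per-group frequencies are fractions of the
group's samples; the recurrence threshold is Q3 + 1.5·IQR of the group's
frequency vector with linear-interpolation quantiles, exceeded strictly.
Hierarchical clustering defaults to the binary character matrix; gene-level
segment profiles can be passed instead.

## Signature scoring and correlation

Normalization is log2(cpm+1) — deliberately simple, because every consumer
(ranking, correlation) depends only on a monotone per-sample transform, and
a model-based variance-stabilizing fit is out of scope.  The score ranks
all N genes ascending with average ties, takes the mean rank of the m set
genes and rescales by the attainable extremes μ_min = (m+1)/2,
μ_max = (2N−m+1)/2 to [−0.5, 0.5].  Up-regulated sets only; no down-set
term.  The HER2–FISH check is a Pearson correlation of a gene's normalized
expression against per-duct mean signals/cell, two-sided p from the t
distribution, undefined under 3 ducts or zero variance.

## Problem sizes and determinism

Defaults throughout are desk-scale: 6 chromosomes × 200 genes, 12 samples
per patient, 300 cells per duct, B = 1000 bootstrap resamples, 10–20
replicates in the recovery experiments.  These sizes give the recovery
statistics comfortable margins (pooled arm-event precision/recall ≈ 0.99/1.0
over ten patients; duct grouping 40/40; cross-platform ρ ≈ 0.83 mean) while
keeping any single experiment under a minute.  All randomness flows through
seeded numpy generators — simulators use fixed per-purpose streams derived
from the config seed, the bootstrap takes an explicit seed, and the
parsimony search uses none — so every result in the test suite and the
acceptance script is exactly reproducible.

## Known limitations

- The FISH generator's distributions are qualitative stand-ins; absolute
  classification rates on real images are not validated here.
- The expression→copy-ratio step ignores gene-specific biases (GC, length,
  mappability); the normal-reference ratio removes them only insofar as
  they are shared between tumor and normal sections.
- Modal-state recentering fails if more than half the profiled genome is
  altered (e.g. genome-doubled tumors).
- Arm events are the resolution floor; sub-arm events exist in the
  generator only to exercise the focal filter, and no allele-specific or
  integer copy number is attempted.
- The AU fit uses ordinary least squares over usable scales; very small or
  very large clusters with flat BP profiles are reported degenerate rather
  than extrapolated.
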