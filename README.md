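# ductevo

Clonal evolution of HER2 amplification in single breast ducts: a tested,
reusable pipeline for the single-duct analysis style in which laser-captured
DCIS ducts are profiled by HER2-FISH and 3'-end RNA sequencing, and the
questions are (i) which ducts are HER2-amplified, (ii) which chromosome-arm
copy-number events each duct carries, (iii) how the ducts are related
clonally, and (iv) whether amplified ducts engage an interferon-stimulated
gene (ISG) program.

No per-patient data of this kind is publicly deposited, so the package ships
a first-class synthetic-data module that generates every input with known
ground truth — clone trees carrying arm-level copy-number events,
negative-binomial expression with copy-number dosage, Poisson whole-genome
sequencing (WGS) bins, and per-cell FISH signal tables — and the test suite
scores each analysis stage against that truth.

## What it computes

**FISH classification and duct grouping** (`ductevo.fish`).  Per-cell HER2
probe counts *s* (signals/cell, clipped to 0–10) are classified by Bayes'
rule against two pooled reference distributions with an uninformative prior:

    P(amp | s) = π P(s | amp) / (π P(s | amp) + (1 − π) P(s | noamp)),  π = ½,

with Laplace-smoothed reference pmfs.  Each duct's signal distribution is
summarized by a Gaussian KDE on a 101-point grid over [0, 10]; ducts are
grouped DCIS_noamp / DCIS_int / DCIS_amp by total-variation distance to the
two references, with a relative margin below τ = 0.15 called ambiguous
(DCIS_int).  A PCA of the density matrix is attached as a QC view.

**Arm-level CNV inference** (`ductevo.cnv`).  Gene-level counts become log2
copy ratios against the patient's own normal samples (cpm ratio with
pseudocount, median-recentered).  All samples of a patient are segmented
*jointly* — an exact dynamic program finds the common breakpoints minimizing
total within-segment squared error plus a per-breakpoint penalty γ.  Copy
states follow the fixed ladder deletion < log2(0.75), loss < log2(0.875),
gain > log2(1.125), amplification > log2(1.25); focal calls under 10 Mb are
removed; same-state neighbors merge; an arm is called gained/lost when ≥50%
of its length is in altered segments (chr1–15 by convention).  Expression
calls are validated by a white-Gaussian-noise consensus: the pipeline is
rerun on counts + N(0, 1) and counts + N(0.5, 1.5), and an event must appear
in ≥2 of the 3 runs.  A 100-kbp-bin WGS path and a gene-level Spearman
cross-platform comparison mirror the expression path, plus a 0.5-Mb block
view of relative expression along a chromosome.

**Clonal phylogeny and recurrence** (`ductevo.phylo`).  Samples are coded as
binary (arm, direction) characters and related by maximum parsimony with an
all-neutral normal root (exact enumeration to 7 leaves; a deterministic
SPR hill-climb above).  Cluster support uses the approximately-unbiased (AU)
p-value from multiscale bootstrap (scales 0.5–1.4, B resamples per scale);
clusters with AU ≥ 0.95 are flagged.  Event statistics follow the
≥2-samples-per-group calling rule, shared / unique-to-group categorization,
and the recurrence fence Q3 + 1.5·IQR on per-group event frequencies.

**Signature scoring** (`ductevo.scoring`).  Counts are normalized as
log2(cpm+1) and a gene set is scored per sample by a rank statistic: the
mean rank of the set genes, rescaled to [−0.5, 0.5] so the bounds are hit
exactly when the set occupies the extreme ranks.  The HER2 expression vs
mean FISH signals/cell Pearson correlation across ducts is also provided.

## Worked example

Run the full synthetic pipeline (simulate → FISH → CNV → phylogeny → score):

```
ductevo run --outdir demo --seed 1
# run complete: 20 outputs in demo
```

The default cohort is one patient with a normal clone and two tumor clones
in a chain (noamp → amp), four samples each, four arm events.  Selected
outputs from this exact run:

- `tree.nwk` — the parsimony tree with per-branch events in comments:

      (clone1_s1,clone1_s2,clone1_s3,clone1_s4,
       (clone2_s1,...,clone2_s4)[&events=6q:gain+])[&events=3p:gain+|3q:loss+|6p:loss+];

  All eight tumor samples share three events (the trunk); the amplified
  clone's samples form a clade defined by an extra 6q gain.  The parsimony
  score 4 equals the number of simulated events.

- `her2_fish_correlation.json` — HER2-analog expression vs mean FISH
  signal/cell across the eight tumor ducts: `r = 0.934, p = 6.9e-4, n = 8`.

- `event_summary.json` — `shared: 75%, unique_amp: 25%, unique_noamp: 0%`:
  the trunk events are shared by both duct groups, the 6q gain is unique to
  the amplified group, matching the simulated tree.

- `signature_scores.tsv` — ISG-like rank scores: normal samples near 0
  (−0.05 to −0.02), amplified-clone samples elevated (≈ 0.21–0.24), since
  the generator applies a 3-fold signature effect to amp samples.

- `duct_groups.tsv` — per-duct grouping with distances and margins, e.g.
  `clone1_s2  DCIS_noamp  d_no=0.048  d_amp=0.699  margin=0.87`.

Every run writes a `manifest.json` with the seed, all parameter values, and
SHA-256 hashes of each output; two runs with the same seed are byte-identical.

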