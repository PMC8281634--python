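"""Arm-level copy-number inference from expression or shallow-WGS counts.

The pipeline turns per-gene read counts (or fixed-width WGS bin counts) into
log2 copy ratios against the patient's own normal samples, segments all
samples of a patient jointly so breakpoints are shared, calls discrete copy
states with fixed log2 cutoffs, removes focal (<10 Mb) calls, merges
same-state neighbors, reduces segments to chromosome-arm gain/loss events,
and validates expression-based calls with a white-Gaussian-noise consensus
(an event must recur in >=2 of 3 datasets: original plus two noise-injected
copies).  Small chromosomes can be excluded (the field convention here is
chr1-15) because few genes make their log2 ratios unstable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinProfiles",
    "Segment",
    "ArmEvent",
    "CNV_CUTOFFS",
    "DEFAULT_CHROMOSOMES",
    "expression_to_bins",
    "wgs_to_bins",
    "multisample_segment",
    "call_states",
    "filter_and_merge",
    "segments_to_arm_events",
    "noise_consensus",
    "expression_pipeline",
    "chr17_blocks",
    "cross_platform_correlation",
]

# log2 copy-ratio ladder: deletion < log2(0.75); loss < log2(0.875);
# gain > log2(1.125); amplification > log2(1.25); neutral otherwise.
CNV_CUTOFFS = {
    "deletion": np.log2(0.75),
    "loss": np.log2(0.875),
    "gain": np.log2(1.125),
    "amplification": np.log2(1.25),
}

DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 16))


def _chrom_key(chrom: str):
    m = re.search(r"(\d+)$", chrom)
    return (0, int(m.group(1))) if m else (1, chrom)


@dataclass
class BinProfiles:
    """Log2 copy-ratio profiles of all samples of one patient on a shared
    locus grid (genes ordered by transcription termination site, or fixed
    bins ordered by start)."""

    loci: pd.DataFrame  # columns: id, chrom, pos
    values: np.ndarray  # loci x samples
    samples: list[str]
    source: str  # "expression" or "wgs"

    def __post_init__(self):
        if self.values.shape != (len(self.loci), len(self.samples)):
            raise ValueError("values shape does not match loci x samples")

    def frame(self) -> pd.DataFrame:
        out = self.loci.copy()
        for j, s in enumerate(self.samples):
            out[s] = self.values[:, j]
        return out


@dataclass(frozen=True)
class Segment:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_loci: int
    mean_log2: float
    state: str | None = None


@dataclass(frozen=True)
class ArmEvent:
    arm: str
    direction: str  # gain / loss
    sample_id: str
    covered_fraction: float


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size in samples: {bad}")
    return counts / totals * 1e6


def expression_to_bins(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> BinProfiles:
    """Per-gene log2 copy ratios against the patient's normal samples.

    Counts are scaled to counts-per-million; the ratio for gene g in sample
    s is log2((cpm_gs + c) / (mean over normals of cpm_g + c)) with
    pseudocount c, re-centered by the sample's median log2 ratio
    (library-size normalization in aneuploid samples shifts neutral loci
    away from zero because gains and losses change the total expressed
    mass; median centering is the standard correction).  Genes absent from
    the annotation are dropped with a
    warning; genes with zero counts across all normals are dropped for the
    whole patient.  Loci are ordered by (chromosome, transcription
    termination site).
    """
    normals = list(normal_sample_ids)
    if not normals:
        raise ValueError("at least one normal sample is required")
    missing = set(counts.index) - set(annotation["gene_id"])
    if missing:
        warnings.warn(f"{len(missing)} counted genes missing from annotation; dropped")
    ann = annotation.set_index("gene_id").loc[
        [g for g in counts.index if g in set(annotation["gene_id"])]
    ]
    counts = counts.loc[ann.index]
    keep = counts[normals].sum(axis=1) > 0
    counts, ann = counts[keep], ann[keep]
    cpm = _cpm(counts)
    ref = cpm[normals].mean(axis=1)
    r = np.log2(cpm.add(pseudocount, axis=0).div(ref + pseudocount, axis=0))
    r = r - r.median(axis=0)
    order = sorted(range(len(ann)), key=lambda i: (_chrom_key(ann["chrom"].iloc[i]), ann["tts"].iloc[i]))
    ann, r = ann.iloc[order], r.iloc[order]
    loci = pd.DataFrame(
        {"id": ann.index, "chrom": ann["chrom"].to_numpy(), "pos": ann["tts"].to_numpy()}
    ).reset_index(drop=True)
    return BinProfiles(loci=loci, values=r.to_numpy(), samples=list(r.columns), source="expression")


def wgs_to_bins(
    bin_counts: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> BinProfiles:
    """Fixed-width WGS bin counts to log2 copy ratios vs the normal mean.

    ``bin_counts`` must carry 'chrom' and 'start' columns plus one column
    per sample on a common bin grid.  Counts are depth-normalized to
    counts-per-million before the ratio; bins with zero coverage across all
    normals are dropped.
    """
    normals = list(normal_sample_ids)
    if not normals:
        raise ValueError("at least one normal sample is required")
    samples = [c for c in bin_counts.columns if c not in ("chrom", "start")]
    counts = bin_counts[samples]
    keep = counts[normals].sum(axis=1) > 0
    bc = bin_counts[keep].reset_index(drop=True)
    cpm = _cpm(bc[samples])
    ref = cpm[normals].mean(axis=1)
    r = np.log2(cpm.add(pseudocount, axis=0).div(ref + pseudocount, axis=0))
    r = r - r.median(axis=0)
    order = sorted(range(len(bc)), key=lambda i: (_chrom_key(bc["chrom"].iloc[i]), bc["start"].iloc[i]))
    bc, r = bc.iloc[order], r.iloc[order]
    loci = pd.DataFrame(
        {
            "id": [f"{c}:{s}" for c, s in zip(bc["chrom"], bc["start"])],
            "chrom": bc["chrom"].to_numpy(),
            "pos": bc["start"].to_numpy(),
        }
    ).reset_index(drop=True)
    return BinProfiles(loci=loci, values=r.to_numpy(), samples=samples, source="wgs")


def _noise_variance(x: np.ndarray) -> float:
    """Robust per-locus noise variance from first differences.

    For i.i.d. Gaussian noise the successive differences have variance
    2*sigma^2 and their squares have median 2*sigma^2*0.4549.
    """
    if x.shape[0] < 3:
        return float(np.var(x)) if x.size else 1.0
    d = np.diff(x, axis=0)
    med = float(np.median(d**2))
    return max(med / (2 * 0.454936), 1e-12)


def _segment_chromosome(x: np.ndarray, gamma: float, min_seg: int) -> list[int]:
    """Exact DP for shared-breakpoint least-squares segmentation.

    Minimizes sum over samples of within-segment squared deviations plus
    gamma per breakpoint, over segmentations common to all samples.
    Returns interior breakpoint indices (a breakpoint at k splits loci
    [0,k) and [k,n)).
    """
    n = x.shape[0]
    if n < 2 * min_seg:
        return []
    cum = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    cumsq = np.vstack([np.zeros(x.shape[1]), np.cumsum(x**2, axis=0)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # total SSE of segment [i, j) summed over samples, vectorized in i
        length = (j - i).astype(float)
        ssum = cum[j] - cum[i]
        ssq = cumsq[j] - cumsq[i]
        return (ssq - ssum**2 / length[:, None]).sum(axis=1)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment pays no breakpoint penalty
    for j in range(min_seg, n + 1):
        starts = np.arange(0, j - min_seg + 1)
        cand = best[starts] + seg_cost(starts, j) + gamma
        k = int(np.argmin(cand))
        best[j], prev[j] = cand[k], starts[k]
    bps = []
    j = n
    while j > 0:
        if prev[j] > 0:
            bps.append(int(prev[j]))
        j = prev[j]
    return sorted(bps)


def multisample_segment(
    profiles: BinProfiles,
    gamma: float | None = None,
    min_seg: int = 5,
    chrom_sizes: dict[str, int] | None = None,
    recenter: bool = True,
) -> tuple[dict[str, list[int]], list[Segment]]:
    """Joint piecewise-constant segmentation of all samples of a patient.

    Per chromosome an exact O(n^2) dynamic program finds the breakpoint set
    shared by every sample that minimizes total within-segment squared
    deviation plus ``gamma`` per breakpoint.  When ``gamma`` is None a
    BIC-style default 2 * n_samples * sigma^2 * ln(n_loci) is used with a
    robust first-difference noise-variance estimate.  Segment boundaries in
    bp are the midpoints between flanking loci; chromosome ends extend to
    [0, length) when ``chrom_sizes`` is given, else to the locus span.

    With ``recenter`` (default) each sample's segment means are shifted so
    the locus-weighted median segment level is zero, anchoring the modal
    copy state at neutral.  Locus-level centering cannot do this reliably:
    per-locus noise is comparable to the copy-number signal, so a third of
    the genome gained already drags the locus median off the neutral level,
    while segment means average that noise away.  This assumes at least
    half of the profiled loci are copy-neutral.

    Returns (breakpoints per chromosome as locus indices, segments with
    per-sample mean log2).
    """
    if min_seg < 1:
        raise ValueError("min_seg must be >= 1")
    if gamma is not None and gamma <= 0:
        raise ValueError("gamma must be positive")
    chroms = list(dict.fromkeys(profiles.loci["chrom"]))
    breakpoints: dict[str, list[int]] = {}
    segments: list[Segment] = []
    for chrom in chroms:
        mask = (profiles.loci["chrom"] == chrom).to_numpy()
        x = profiles.values[mask]
        pos = profiles.loci["pos"].to_numpy()[mask]
        n = x.shape[0]
        g = gamma
        if g is None:
            sigma2 = _noise_variance(x)
            g = 2.0 * x.shape[1] * sigma2 * max(np.log(n), 1.0)
        bps = _segment_chromosome(x, g, min_seg) if n >= min_seg else []
        breakpoints[chrom] = bps
        bounds = [0] + bps + [n]
        if chrom_sizes is not None and chrom in chrom_sizes:
            span_start, span_end = 0, int(chrom_sizes[chrom])
        else:
            span_start, span_end = int(pos[0]), int(pos[-1]) + 1
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = span_start if a == 0 else int((pos[a - 1] + pos[a]) // 2)
            end = span_end if b == n else int((pos[b - 1] + pos[b]) // 2)
            means = x[a:b].mean(axis=0)
            for j, s in enumerate(profiles.samples):
                segments.append(
                    Segment(
                        sample_id=s,
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_loci=b - a,
                        mean_log2=float(means[j]),
                    )
                )
    if recenter and segments:
        by_sample: dict[str, list[int]] = {}
        for k, s in enumerate(segments):
            by_sample.setdefault(s.sample_id, []).append(k)
        for sample, idxs in by_sample.items():
            levels = np.concatenate(
                [np.full(segments[k].n_loci, segments[k].mean_log2) for k in idxs]
            )
            shift = float(np.median(levels))
            for k in idxs:
                segments[k] = replace(segments[k], mean_log2=segments[k].mean_log2 - shift)
    return breakpoints, segments


def call_states(segments: Iterable[Segment]) -> list[Segment]:
    """Assign copy states from mean log2 by the fixed cutoff ladder.

    Strict inequalities; a mean exactly at a cutoff takes the less extreme
    state.
    """
    out = []
    for seg in segments:
        m = seg.mean_log2
        if not np.isfinite(m):
            raise ValueError("segment mean_log2 must be finite")
        if m < CNV_CUTOFFS["deletion"]:
            state = "deletion"
        elif m < CNV_CUTOFFS["loss"]:
            state = "loss"
        elif m > CNV_CUTOFFS["amplification"]:
            state = "amplification"
        elif m > CNV_CUTOFFS["gain"]:
            state = "gain"
        else:
            state = "neutral"
        out.append(replace(seg, state=state))
    return out


def filter_and_merge(segments: Iterable[Segment], min_len: int = 10_000_000) -> list[Segment]:
    """Remove focal calls and merge same-state neighbors.

    Non-neutral segments shorter than ``min_len`` bp (strict) are reset to
    neutral; adjacent segments of a sample/chromosome with identical state
    are then merged with a locus-weighted mean.  Idempotent.
    """
    filtered = [
        replace(s, state="neutral")
        if s.state != "neutral" and (s.end - s.start) < min_len
        else s
        for s in segments
    ]
    out: list[Segment] = []
    keyfn = lambda s: (s.sample_id, _chrom_key(s.chrom), s.start)
    for seg in sorted(filtered, key=keyfn):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.sample_id == seg.sample_id
            and prev.chrom == seg.chrom
            and prev.state == seg.state
            and prev.end == seg.start
        ):
            n = prev.n_loci + seg.n_loci
            mean = (prev.mean_log2 * prev.n_loci + seg.mean_log2 * seg.n_loci) / n
            out[-1] = replace(prev, end=seg.end, n_loci=n, mean_log2=mean)
        else:
            out.append(seg)
    return out


def segments_to_arm_events(
    segments: Iterable[Segment],
    arms: pd.DataFrame,
    coverage_threshold: float = 0.5,
    chromosomes: Sequence[str] | None = DEFAULT_CHROMOSOMES,
) -> list[ArmEvent]:
    """Reduce state-called segments to arm-level gain/loss events.

    An arm is called gained (lost) in a sample when at least
    ``coverage_threshold`` of its length lies in gain/amplification
    (loss/deletion) segments.  ``arms`` carries (arm, chrom, start, end).
    Chromosomes outside the restriction list are excluded; pass None to
    keep all.
    """
    segs = [s for s in segments if s.state is not None]
    if chromosomes is not None:
        allowed = set(chromosomes)
        segs = [s for s in segs if s.chrom in allowed]
        arms = arms[arms["chrom"].isin(allowed)]
    by_sample_chrom: dict[tuple[str, str], list[Segment]] = {}
    for s in segs:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    events: list[ArmEvent] = []
    samples = sorted({s.sample_id for s in segs})
    for sample in samples:
        for _, armrow in arms.iterrows():
            chrom_segs = by_sample_chrom.get((sample, armrow["chrom"]), [])
            arm_len = armrow["end"] - armrow["start"]
            gain_len = loss_len = 0
            for seg in chrom_segs:
                ov = min(seg.end, armrow["end"]) - max(seg.start, armrow["start"])
                if ov <= 0:
                    continue
                if seg.state in ("gain", "amplification"):
                    gain_len += ov
                elif seg.state in ("loss", "deletion"):
                    loss_len += ov
            gf, lf = gain_len / arm_len, loss_len / arm_len
            assert not (gf >= coverage_threshold and lf >= coverage_threshold and coverage_threshold > 0.5), (
                "gain and loss cannot both dominate an arm"
            )
            if gf >= coverage_threshold and gf >= lf:
                events.append(ArmEvent(armrow["arm"], "gain", sample, gf))
            elif lf >= coverage_threshold:
                events.append(ArmEvent(armrow["arm"], "loss", sample, lf))
    return events


def expression_pipeline(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    arms: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    gamma: float | None = None,
    min_seg: int = 5,
    min_len: int = 10_000_000,
    coverage_threshold: float = 0.5,
    chromosomes: Sequence[str] | None = DEFAULT_CHROMOSOMES,
) -> tuple[list[Segment], list[ArmEvent]]:
    """Full expression path: bins -> joint segmentation -> states -> focal
    filter/merge -> arm events.  Returns (segments, arm events)."""
    profiles = expression_to_bins(counts, annotation, normal_sample_ids)
    _, segments = multisample_segment(profiles, gamma=gamma, min_seg=min_seg, chrom_sizes=chrom_sizes)
    segments = filter_and_merge(call_states(segments), min_len=min_len)
    events = segments_to_arm_events(segments, arms, coverage_threshold, chromosomes)
    return segments, events


def noise_consensus(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    arms: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    seeds: tuple[int, int] = (101, 102),
    **pipeline_kwargs,
) -> tuple[list[ArmEvent], dict]:
    """White-Gaussian-noise consensus filter for expression-based calls.

    The full pipeline runs on the original counts and on two noise-injected
    copies — N(0, 1) and N(0.5, 1.5) added to the raw counts, negatives
    clipped to 0 — and an arm event is retained only if the same
    (sample, arm, direction) appears in at least 2 of the 3 runs.  Returns
    (consensus events with covered_fraction from the original run where
    available, report dict with per-run event keys and seeds).
    """
    noise_settings = [(0.0, 1.0), (0.5, 1.5)]
    datasets = [counts]
    for (mu, sd), seed in zip(noise_settings, seeds):
        rng = np.random.default_rng(seed)
        noisy = counts.to_numpy(dtype=float) + rng.normal(mu, sd, size=counts.shape)
        datasets.append(
            pd.DataFrame(np.clip(noisy, 0, None), index=counts.index, columns=counts.columns)
        )
    run_events = []
    for data in datasets:
        _, events = expression_pipeline(
            data, annotation, normal_sample_ids, arms, chrom_sizes, **pipeline_kwargs
        )
        run_events.append(events)
    keysets = [{(e.sample_id, e.arm, e.direction) for e in ev} for ev in run_events]
    counts_by_key: dict[tuple, int] = {}
    for ks in keysets:
        for k in ks:
            counts_by_key[k] = counts_by_key.get(k, 0) + 1
    consensus_keys = {k for k, c in counts_by_key.items() if c >= 2}
    by_key = {(e.sample_id, e.arm, e.direction): e for ev in reversed(run_events) for e in ev}
    consensus = sorted(
        (by_key[k] for k in consensus_keys), key=lambda e: (e.sample_id, e.arm, e.direction)
    )
    report = {
        "seeds": list(seeds),
        "noise_settings": noise_settings,
        "runs": [sorted(f"{s}|{a}|{d}" for s, a, d in ks) for ks in keysets],
        "consensus": sorted(f"{s}|{a}|{d}" for s, a, d in consensus_keys),
    }
    return consensus, report


def chr17_blocks(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    chrom: str = "chr17",
    block_size: int = 500_000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Relative expression aggregated in fixed blocks along one chromosome.

    Genes are assigned to half-open blocks [k*block_size, (k+1)*block_size)
    by transcription termination site; a block's value per sample is
    log2(mean over member genes of (cpm + c) / (normal-mean cpm + c)).
    Blocks without genes are missing (NaN rows are omitted); the index is
    the block start coordinate.
    """
    normals = list(normal_sample_ids)
    if not normals:
        raise ValueError("at least one normal sample is required")
    ann = annotation[annotation["chrom"] == chrom]
    if ann.empty:
        warnings.warn(f"no genes on {chrom}")
        return pd.DataFrame(columns=counts.columns)
    shared = [g for g in ann["gene_id"] if g in counts.index]
    ann = ann.set_index("gene_id").loc[shared]
    cpm = _cpm(counts)
    sub = cpm.loc[shared]
    ref = sub[normals].mean(axis=1)
    ratio = sub.add(pseudocount, axis=0).div(ref + pseudocount, axis=0)
    block = (ann["tts"] // block_size).astype(int) * block_size
    grouped = np.log2(ratio.groupby(block.to_numpy()).mean())
    grouped.index.name = "block_start"
    return grouped.sort_index()


def _genes_to_segment_values(
    segments: Iterable[Segment], annotation: pd.DataFrame, chromosomes: Sequence[str] | None
) -> pd.DataFrame:
    ann = annotation
    if chromosomes is not None:
        ann = ann[ann["chrom"].isin(set(chromosomes))]
    rows = {}
    by_sample: dict[str, list[Segment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    for sample, segs in by_sample.items():
        vals = {}
        for _, g in ann.iterrows():
            for seg in segs:
                if seg.chrom == g["chrom"] and seg.start <= g["tts"] < seg.end:
                    vals[g["gene_id"]] = seg.mean_log2
                    break
        rows[sample] = vals
    return pd.DataFrame(rows)


def cross_platform_correlation(
    seg_expr: Iterable[Segment],
    seg_wgs: Iterable[Segment],
    annotation: pd.DataFrame,
    chromosomes: Sequence[str] | None = DEFAULT_CHROMOSOMES,
    min_genes: int = 10,
) -> pd.Series:
    """Per-sample Spearman correlation of gene-level segment log2 values.

    Each gene inherits the mean log2 of its covering segment on each
    platform; the correlation runs over genes covered on both.  Samples with
    fewer than ``min_genes`` shared genes get NaN.
    """
    ge = _genes_to_segment_values(seg_expr, annotation, chromosomes)
    gw = _genes_to_segment_values(seg_wgs, annotation, chromosomes)
    out = {}
    for sample in ge.columns:
        if sample not in gw.columns:
            continue
        both = pd.concat([ge[sample], gw[sample]], axis=1, join="inner").dropna()
        if len(both) < min_genes:
            out[sample] = np.nan
            continue
        rho = stats.spearmanr(both.iloc[:, 0], both.iloc[:, 1]).statistic
        out[sample] = float(rho)
    return pd.Series(out, name="spearman_rho")
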