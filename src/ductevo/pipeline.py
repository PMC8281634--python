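"""End-to-end driver: simulate -> FISH -> CNV -> phylogeny -> scoring.

``run_pipeline`` chains the modules on one synthetic patient, writes every
stage's outputs in the plain-text formats of :mod:`ductevo.io`, and records
a manifest with parameter values, seeds, and content hashes so a run is
fully reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import __version__
from .cnv import DEFAULT_CHROMOSOMES, chr17_blocks, noise_consensus
from .fish import build_reference_density, classify_cells, duct_density, group_ducts
from .phylo import build_characters, event_stats, hclust_au, parsimony_search
from .scoring import expression_fish_correlation, normalize, score_signature
from .synthetic import (
    ROOT_CLONE,
    SimulationConfig,
    assign_samples,
    make_clone_tree,
    make_genome,
    simulate_expression,
    simulate_fish,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters with their conventional defaults.

    The CNV cutoff ladder, 10 Mb focal filter, 0-10 FISH signal support,
    2-of-3 noise consensus, >=2-samples-per-group event calling, AU >= 0.95
    support flag, Q3 + 1.5*IQR recurrence fence, 0.5 Mb expression blocks,
    100 kbp WGS bins and the chr1-15 restriction are the field conventions
    this pipeline follows; the remaining knobs (tau, alpha, gamma, min_seg,
    B, scales) are this package's own and are exposed here.
    """

    seed: int = 0
    # synthetic cohort
    n_clones: int = 3
    n_events: int = 4
    topology: str = "chain"  # amp clone evolves from the noamp clone
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fish_cells_per_duct: int = 300
    # fish model
    tau: float = 0.15
    alpha: float = 1.0
    prior: float = 0.5
    # cnv caller
    gamma: float | None = None
    min_seg: int = 5
    min_len: int = 10_000_000
    coverage_threshold: float = 0.5
    chromosomes: tuple | None = None  # None -> all simulated (<= chr15 anyway)
    consensus: bool = True
    block_size: int = 500_000
    # phylogeny
    min_samples: int = 2
    parsimony_mode: str = "auto"
    au_B: int = 1000
    au_scales: tuple = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))
    run_au: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["fish_params"] = {
            k: list(np.asarray(v, dtype=float))
            for k, v in d["simulation"]["fish_params"].items()
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _amp_clones(tree) -> set[str]:
    """Clones with the largest total copy-number burden play the DCIS_amp
    role (amplification is acquired, so the most-altered clones are 'amp')."""
    burden = {
        c: sum(abs(cn - 2) for cn in prof.values())
        for c, prof in tree.clone_profile.items()
        if c != ROOT_CLONE
    }
    top = max(burden.values())
    return {c for c, b in burden.items() if b == top}


def _her2_analog(genome, tree, amp_clones) -> str:
    """A gene on an arm gained in the amp clones: the HER2 stand-in whose
    expression should track the FISH signal (it additionally receives the
    focal ``her2_fold`` amplification in amp samples)."""
    gained_amp = set()
    gained_other = set()
    for c, prof in tree.clone_profile.items():
        if c == ROOT_CLONE:
            continue
        for arm, cn in prof.items():
            if cn > 2:
                (gained_amp if c in amp_clones else gained_other).add(arm)
    candidates = sorted(gained_amp - gained_other) or sorted(gained_amp)
    if candidates:
        genes = genome.genes[genome.genes["arm"] == candidates[0]]
        if not genes.empty:
            return str(genes["gene_id"].iloc[0])
    return str(genome.genes["gene_id"].iloc[0])


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full synthetic analysis and write all outputs to ``outdir``.

    Returns the manifest dict (also written to manifest.json).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)

    # --- simulate ---------------------------------------------------------
    genome = make_genome(sim)
    tree = make_clone_tree(
        sim,
        n_clones=config.n_clones,
        n_events=config.n_events,
        genome=genome,
        topology=config.topology,
    )
    assignment = assign_samples(tree, sim.samples_per_clone)
    amp_clones = _amp_clones(tree)
    her2_gene = _her2_analog(genome, tree, amp_clones)
    counts, truth = simulate_expression(
        genome, tree, sim, assignment, amp_clones=amp_clones, her2_gene=her2_gene
    )
    tumor_samples = [s for s, c in assignment.items() if c != ROOT_CLONE]
    normal_samples = [s for s, c in assignment.items() if c == ROOT_CLONE]
    duct_specs = [
        (s, "amp" if assignment[s] in amp_clones else "noamp", config.fish_cells_per_duct)
        for s in tumor_samples
    ]
    cells, fish_truth = simulate_fish(sim, duct_specs)
    ref_sim = dataclasses.replace(sim, seed=config.seed + 1)
    ref_cells, _ = simulate_fish(
        ref_sim,
        [("ref_no", "noamp", 2000), ("ref_amp", "amp", 2000)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": list(assignment),
            "patient": "P1",
            "clone": [assignment[s] for s in assignment],
            "sample_type": [truth["groups"][s] for s in assignment],
        }
    )
    dio.write_counts(counts, out / "counts.tsv")
    dio.write_annotation(genome.genes, out / "annotation.tsv")
    dio.write_chrom_table(genome.chromosomes, out / "chromosomes.tsv")
    dio.write_fish_cells(cells, out / "fish_cells.csv")
    dio.write_metadata(meta, out / "metadata.tsv")
    dio.write_gene_set(truth["signature_genes"], out / "signature_genes.txt")
    dio.write_json(
        {k: v for k, v in truth.items() if k != "library_sizes"}, out / "truth.json"
    )

    # --- FISH classification and duct grouping ----------------------------
    ref_no = build_reference_density(
        ref_cells[ref_cells["duct_id"] == "ref_no"], "noamp", alpha=config.alpha
    )
    ref_amp = build_reference_density(
        ref_cells[ref_cells["duct_id"] == "ref_amp"], "amp", alpha=config.alpha
    )
    posteriors = classify_cells(cells, ref_no, ref_amp, prior=config.prior)
    posteriors.to_csv(out / "cell_posteriors.csv", index=False)
    densities = [
        duct_density(cells[cells["duct_id"] == d], duct_id=d, alpha=config.alpha)
        for d in cells["duct_id"].unique()
    ]
    groups = group_ducts(densities, ref_no, ref_amp, tau=config.tau)
    pd.DataFrame(
        [
            (g.duct_id, g.group, g.d_noamp, g.d_amp, g.margin, g.pc1, g.pc2)
            for g in groups
        ],
        columns=["duct_id", "group", "d_noamp", "d_amp", "margin", "pc1", "pc2"],
    ).to_csv(out / "duct_groups.tsv", sep="\t", index=False)
    dens_mat = pd.DataFrame(
        np.vstack([d.density for d in densities]),
        index=[d.duct_id for d in densities],
        columns=[f"s{g:.1f}" for g in densities[0].grid],
    )
    dens_mat.rename_axis("duct_id").to_csv(out / "duct_densities.tsv", sep="\t")

    # --- CNV inference ----------------------------------------------------
    arms = genome.arms()
    chroms = config.chromosomes
    if chroms is None:
        chroms = tuple(c for c in genome.chromosomes["chrom"] if c in DEFAULT_CHROMOSOMES)
    kwargs = dict(
        gamma=config.gamma,
        min_seg=config.min_seg,
        min_len=config.min_len,
        coverage_threshold=config.coverage_threshold,
        chromosomes=chroms,
    )
    from .cnv import expression_pipeline

    segments, raw_events = expression_pipeline(
        counts, genome.genes, normal_samples, arms, genome.chrom_sizes(), **kwargs
    )
    if config.consensus:
        events, report = noise_consensus(
            counts,
            genome.genes,
            normal_samples,
            arms,
            genome.chrom_sizes(),
            seeds=(config.seed * 2 + 101, config.seed * 2 + 102),
            **kwargs,
        )
        dio.write_json(report, out / "consensus_report.json")
    else:
        events = raw_events
    dio.write_seg(segments, out / "segments.seg")
    dio.write_arm_events(events, out / "arm_events.tsv")
    blocks = chr17_blocks(
        counts,
        genome.genes,
        normal_samples,
        chrom=str(genome.chromosomes["chrom"].iloc[0]),
        block_size=config.block_size,
    )
    blocks.to_csv(out / "block_matrix.tsv", sep="\t")

    # --- phylogeny --------------------------------------------------------
    matrix = build_characters(events, tumor_samples)
    ptree = parsimony_search(matrix, mode=config.parsimony_mode)
    (out / "tree.nwk").write_text(dio.newick_with_events(ptree) + "\n")
    support = None
    if config.run_au and len(matrix) >= 3 and matrix.shape[1] >= 2:
        support = hclust_au(matrix, B=config.au_B, scales=config.au_scales, seed=config.seed)
        dio.write_json(
            {
                "settings": support.settings,
                "clusters": support.table.to_dict(orient="records"),
            },
            out / "cluster_support.json",
        )
    sample_groups = {s: truth["groups"][s] for s in tumor_samples}
    estats = event_stats(events, sample_groups, min_samples=config.min_samples)
    freq = estats.frequencies.copy()
    freq.index = [f"{a}:{d}" for a, d in freq.index] if len(freq) else freq.index
    freq.rename_axis("event").to_csv(out / "event_stats.tsv", sep="\t")
    dio.write_json(
        {
            "category_percent": estats.category_percent,
            "thresholds": estats.thresholds,
            "recurrent": {g: [f"{a}:{d}" for a, d in ev] for g, ev in estats.recurrent.items()},
        },
        out / "event_summary.json",
    )

    # --- signature scoring and HER2/FISH correlation ----------------------
    norm_mat = normalize(counts)
    scores = score_signature(norm_mat, truth["signature_genes"], set_id="isg_like")
    scores.to_csv(out / "signature_scores.tsv", sep="\t", index=False)
    mean_fish = cells.groupby("duct_id")["her2_signals"].mean()
    corr = expression_fish_correlation(norm_mat.loc[her2_gene, tumor_samples], mean_fish)
    dio.write_json({"gene": her2_gene, **corr}, out / "her2_fish_correlation.json")

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "parsimony_score": ptree.score,
        "n_consensus_events": len(events),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
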