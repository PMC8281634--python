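"""Synthetic cohorts with known ground truth.

Generates the inputs the downstream analysis consumes: a toy genome with
chromosome arms, a clonal tree carrying arm-level copy-number events,
negative-binomial expression counts with copy-number dosage, Poisson WGS
bin counts, and per-cell FISH signal tables for non-amplified /
intermediate / amplified ducts.  Every simulator is deterministic for a
fixed seed and returns its ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticGenome",
    "CloneTree",
    "SimulationConfig",
    "make_genome",
    "make_clone_tree",
    "assign_samples",
    "simulate_expression",
    "simulate_fish",
    "simulate_wgs_bins",
    "DEFAULT_FISH_PMFS",
    "sample_tree_newick",
]

ROOT_CLONE = "normal"

# Per-cell HER2 signal distributions over 0..10 signals/cell.  Non-amplified
# ducts concentrate on 1-3 signals/cell; amplified ducts are wide with most
# mass at >=4; intermediate ducts are an equal mixture of the two cell
# populations.  Control probes sit near 2 signals/cell.
_NOAMP_PMF = np.array(
    [0.02, 0.28, 0.36, 0.20, 0.07, 0.03, 0.02, 0.01, 0.005, 0.003, 0.002]
)
_AMP_PMF = np.array(
    [0.005, 0.02, 0.05, 0.08, 0.12, 0.14, 0.15, 0.14, 0.12, 0.09, 0.085]
)
DEFAULT_FISH_PMFS = {
    "noamp": _NOAMP_PMF / _NOAMP_PMF.sum(),
    "amp": _AMP_PMF / _AMP_PMF.sum(),
    "control": np.array([0.03, 0.12, 0.70, 0.12, 0.03]),
}


@dataclass(frozen=True)
class SyntheticGenome:
    """Chromosome coordinates and gene annotation for a simulated genome.

    ``chromosomes`` holds (name, length bp, centromere bp); ``genes`` is a
    DataFrame with columns gene_id, chrom, tts (transcription termination
    site, 0-based), arm.  Positions are 0-based.
    """

    chromosomes: pd.DataFrame  # columns: chrom, length, centromere
    genes: pd.DataFrame  # columns: gene_id, chrom, tts, arm

    def arms(self) -> pd.DataFrame:
        """Arm intervals as rows (arm, chrom, start, end), 0-based half-open."""
        rows = []
        for _, c in self.chromosomes.iterrows():
            num = c["chrom"].replace("chr", "")
            rows.append((f"{num}p", c["chrom"], 0, int(c["centromere"])))
            rows.append((f"{num}q", c["chrom"], int(c["centromere"]), int(c["length"])))
        return pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])

    def chrom_sizes(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["chrom"], self.chromosomes["length"]))


@dataclass
class CloneTree:
    """Clonal tree of arm-level CNV events.

    ``parent`` maps each clone to its parent (root ``normal`` maps to None);
    ``events_on_branch`` maps a clone to the (arm, direction) events gained on
    the branch leading to it; ``clone_profile`` gives the integer copy number
    of every arm in every clone (normal diploid = 2).
    """

    parent: dict[str, str | None]
    events_on_branch: dict[str, list[tuple[str, str]]]
    clone_profile: dict[str, dict[str, int]]

    @property
    def clones(self) -> list[str]:
        return list(self.parent)

    def path_to_root(self, clone: str) -> list[str]:
        path = [clone]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    dispersion is the negative-binomial overdispersion (variance =
    mu + dispersion * mu^2); dosage_exponent beta sets expected expression
    proportional to (CN/2)**beta; library sizes emulate ~1.2 M uniquely
    mapped reads per microdissected sample.
    """

    seed: int = 0
    n_chromosomes: int = 6
    genes_per_chromosome: int = 200
    samples_per_clone: int = 4
    dispersion: float = 0.15
    dosage_exponent: float = 1.0
    library_size_range: tuple[float, float] = (8e5, 1.5e6)
    fish_params: dict = field(default_factory=lambda: dict(DEFAULT_FISH_PMFS))
    signature_fold: float = 3.0
    n_signature_genes: int = 40
    her2_fold: float = 6.0  # focal amplification of the HER2 stand-in in amp samples
    chrom_length_range: tuple[int, int] = (120_000_000, 220_000_000)
    centromere_fraction: float = 0.4

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dosage_exponent <= 0:
            raise ValueError("dosage_exponent must be > 0")
        for key in ("noamp", "amp"):
            pmf = np.asarray(self.fish_params[key], dtype=float)
            if abs(pmf.sum() - 1.0) > 1e-9 or (pmf < 0).any():
                raise ValueError(f"fish pmf {key!r} is not a distribution")


def _stream_rng(seed: int, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream_id)))


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build a deterministic toy genome from the configuration.

    Chromosome lengths are evenly spaced from the top to the bottom of
    ``chrom_length_range`` (largest first, mirroring real karyotype order);
    the centromere sits at ``centromere_fraction`` of the length; gene
    transcription termination sites are uniform on each chromosome.
    """
    config.validate()
    rng = _stream_rng(config.seed, 1)
    n = config.n_chromosomes
    lo, hi = config.chrom_length_range
    lengths = np.linspace(hi, lo, n).astype(np.int64)
    chroms = pd.DataFrame(
        {
            "chrom": [f"chr{i + 1}" for i in range(n)],
            "length": lengths,
            "centromere": (lengths * config.centromere_fraction).astype(np.int64),
        }
    )
    rows = []
    for _, c in chroms.iterrows():
        tts = np.sort(
            rng.choice(int(c["length"]), size=config.genes_per_chromosome, replace=False)
        )
        num = c["chrom"].replace("chr", "")
        for j, pos in enumerate(tts):
            arm = f"{num}p" if pos < c["centromere"] else f"{num}q"
            rows.append((f"{c['chrom']}_g{j:04d}", c["chrom"], int(pos), arm))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tts", "arm"])
    return SyntheticGenome(chromosomes=chroms, genes=genes)


def make_clone_tree(
    config: SimulationConfig,
    n_clones: int,
    n_events: int,
    genome: SyntheticGenome | None = None,
    topology: str = "random",
) -> CloneTree:
    """Random clone tree with ``n_clones`` clones (including the normal root)
    and ``n_events`` arm-level events drawn without replacement from
    arm x {gain, loss}, with each arm used at most once across the whole
    tree (a gain and a loss of the same arm on one lineage would cancel to
    a diploid state and erase the event from the ground truth).  Every
    tumor branch carries at least one event.

    ``topology``: "random" attaches each new clone to a uniformly chosen
    existing clone; "chain" builds the linear normal -> clone1 -> ... ->
    cloneK path in which later clones strictly accumulate events (the
    amplified-evolves-from-non-amplified situation).
    """
    if topology not in ("random", "chain"):
        raise ValueError(f"unknown topology {topology!r}")
    if n_clones < 2:
        raise ValueError("need at least the normal root and one tumor clone")
    if n_events < 1:
        raise ValueError("need at least one event")
    if genome is None:
        genome = make_genome(config)
    arms = list(genome.arms()["arm"])
    if n_events > len(arms):
        raise ValueError(f"{n_events} events exceed {len(arms)} available arms")
    n_branches = n_clones - 1
    if n_events < n_branches:
        raise ValueError("need at least one event per tumor branch")

    rng = _stream_rng(config.seed, 2)
    parent: dict[str, str | None] = {ROOT_CLONE: None}
    clone_names = [f"clone{i + 1}" for i in range(n_branches)]
    for i, name in enumerate(clone_names):
        if topology == "chain":
            parent[name] = ROOT_CLONE if i == 0 else clone_names[i - 1]
        else:
            # first tumor clone hangs off normal; later clones attach anywhere
            choices = [ROOT_CLONE] + clone_names[:i]
            parent[name] = choices[rng.integers(len(choices))]

    picked_arms = [arms[k] for k in rng.choice(len(arms), size=n_events, replace=False)]
    picks = [(a, "gain" if rng.random() < 0.5 else "loss") for a in picked_arms]
    events_on_branch: dict[str, list[tuple[str, str]]] = {c: [] for c in clone_names}
    for i, ev in enumerate(picks):
        if i < n_branches:
            events_on_branch[clone_names[i]].append(ev)
        else:
            events_on_branch[clone_names[rng.integers(n_branches)]].append(ev)

    profile: dict[str, dict[str, int]] = {ROOT_CLONE: {a: 2 for a in arms}}
    order = clone_names  # parents always precede children by construction
    for name in order:
        prof = dict(profile[parent[name]])
        for arm, direction in events_on_branch[name]:
            prof[arm] += 1 if direction == "gain" else -1
        profile[name] = prof
    return CloneTree(parent=parent, events_on_branch=events_on_branch, clone_profile=profile)


def assign_samples(tree: CloneTree, samples_per_clone: int) -> dict[str, str]:
    """Deterministic sample -> clone assignment, ``samples_per_clone`` each."""
    out = {}
    for clone in tree.clones:
        for i in range(samples_per_clone):
            out[f"{clone}_s{i + 1}"] = clone
    return out


def truth_arm_events(
    tree: CloneTree, assignment: dict[str, str]
) -> set[tuple[str, str, str]]:
    """Ground-truth (sample, arm, direction) events implied by clone profiles."""
    out = set()
    for sample, clone in assignment.items():
        for arm, cn in tree.clone_profile[clone].items():
            if cn > 2:
                out.add((sample, arm, "gain"))
            elif cn < 2:
                out.add((sample, arm, "loss"))
    return out


def simulate_expression(
    genome: SyntheticGenome,
    tree: CloneTree,
    config: SimulationConfig,
    assignment: dict[str, str] | None = None,
    amp_clones: Sequence[str] | None = None,
    her2_gene: str | None = None,
):
    """Negative-binomial gene counts with arm-level copy-number dosage.

    The expected count of gene g in sample s is
    ``L_s * p_g * (CN_arm(g),clone(s) / 2) ** beta`` with the configured
    overdispersion; ``p_g`` are lognormal relative expression levels
    normalized to sum to one.  If ``amp_clones`` is given, the configured
    ``signature_fold`` is additionally applied to a random signature gene
    set in samples of those clones (truth lists the genes), and if
    ``her2_gene`` names a gene, its mean is further multiplied by
    ``her2_fold`` in amp samples — HER2 amplification is focal and reaches
    many copies, well beyond the arm-level gain.

    Returns (counts DataFrame genes x samples, truth dict) where truth holds
    the sample assignment, per-sample group, arm copy numbers, signature
    genes and library sizes.
    """
    config.validate()
    if assignment is None:
        assignment = assign_samples(tree, config.samples_per_clone)
    for s, c in assignment.items():
        if c not in tree.parent:
            raise ValueError(f"sample {s} assigned to unknown clone {c}")
    arms_of_genes = genome.genes["arm"].to_numpy()
    known_arms = set(genome.arms()["arm"])
    if not set(arms_of_genes) <= known_arms:
        raise ValueError("gene on a chromosome without a centromere entry")

    rng = _stream_rng(config.seed, 3)
    genes = genome.genes["gene_id"].to_numpy()
    n_genes = len(genes)
    p_g = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    p_g /= p_g.sum()
    sig_idx = np.sort(rng.choice(n_genes, size=min(config.n_signature_genes, n_genes), replace=False))
    amp_clones = set(amp_clones or ())

    samples = list(assignment)
    lo, hi = config.library_size_range
    libsizes = rng.uniform(lo, hi, size=len(samples))
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        clone = assignment[s]
        cn = np.array([tree.clone_profile[clone][a] for a in arms_of_genes], dtype=float)
        mu = libsizes[j] * p_g * (cn / 2.0) ** config.dosage_exponent
        if clone in amp_clones:
            mu = mu.copy()
            if config.signature_fold != 1.0:
                mu[sig_idx] *= config.signature_fold
            if her2_gene is not None:
                mu[np.flatnonzero(genes == her2_gene)] *= config.her2_fold
        if config.dispersion > 0:
            nparam = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(nparam, nparam / (nparam + mu))
        else:
            counts[:, j] = rng.poisson(mu)

    mat = pd.DataFrame(counts, index=genes, columns=samples)
    groups = {}
    for s, c in assignment.items():
        if c == ROOT_CLONE:
            groups[s] = "normal"
        elif c in amp_clones:
            groups[s] = "DCIS_amp"
        else:
            groups[s] = "DCIS_noamp"
    truth = {
        "assignment": dict(assignment),
        "her2_gene": her2_gene,
        "groups": groups,
        "clone_profile": {c: dict(p) for c, p in tree.clone_profile.items()},
        "signature_genes": list(genes[sig_idx]),
        "library_sizes": dict(zip(samples, libsizes)),
        "arm_events": sorted(truth_arm_events(tree, assignment)),
    }
    return mat, truth


def simulate_fish(
    config: SimulationConfig,
    duct_specs: Sequence[tuple[str, str, int]],
):
    """Per-cell FISH signal counts for a list of (duct_id, group, n_cells).

    Groups: ``noamp`` and ``amp`` draw from their reference pmf over 0..10
    signals/cell; ``int`` cells come from an equal mixture of the two
    populations (the per-cell population is kept as truth).  Control-probe
    signals are drawn near 2.  Returns (cells DataFrame, truth dict).
    """
    config.validate()
    rng = _stream_rng(config.seed, 4)
    pmfs = {k: np.asarray(v, dtype=float) for k, v in config.fish_params.items()}
    ctrl = pmfs.get("control", DEFAULT_FISH_PMFS["control"])
    rows = []
    duct_truth = {}
    for duct_id, group, n_cells in duct_specs:
        if group not in ("noamp", "int", "amp"):
            raise ValueError(f"unknown duct group {group!r}")
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if group == "int":
            pop = np.where(rng.random(n_cells) < 0.5, "noamp", "amp")
        else:
            pop = np.full(n_cells, group)
        signals = np.empty(n_cells, dtype=np.int64)
        for g in ("noamp", "amp"):
            mask = pop == g
            if mask.any():
                signals[mask] = rng.choice(11, size=int(mask.sum()), p=pmfs[g])
        control = rng.choice(len(ctrl), size=n_cells, p=ctrl)
        duct_truth[duct_id] = group
        for i in range(n_cells):
            rows.append((duct_id, f"{duct_id}_c{i + 1}", int(signals[i]), int(control[i]), pop[i]))
    cells = pd.DataFrame(
        rows, columns=["duct_id", "cell_id", "her2_signals", "control_signals", "true_population"]
    )
    truth = {"duct_groups": duct_truth}
    return cells[["duct_id", "cell_id", "her2_signals", "control_signals"]], {
        **truth,
        "cell_population": cells["true_population"].to_numpy(),
    }


def simulate_wgs_bins(
    genome: SyntheticGenome,
    tree: CloneTree,
    config: SimulationConfig,
    assignment: dict[str, str] | None = None,
    depth: float = 20.0,
    bin_size: int = 100_000,
):
    """Poisson read counts in fixed-width bins tiling each chromosome.

    Bin b in sample s counts ~ Poisson(depth * CN_b / 2) where CN_b is the
    clone's copy number of the arm containing the bin start.  Returns
    (bin counts DataFrame with chrom/start columns, truth dict with per-bin
    CN per clone).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if assignment is None:
        assignment = assign_samples(tree, config.samples_per_clone)
    rng = _stream_rng(config.seed, 5)
    bins = []
    for _, c in genome.chromosomes.iterrows():
        n_bins = int(np.ceil(c["length"] / bin_size))
        num = c["chrom"].replace("chr", "")
        for k in range(n_bins):
            start = k * bin_size
            arm = f"{num}p" if start < c["centromere"] else f"{num}q"
            bins.append((c["chrom"], start, arm))
    bframe = pd.DataFrame(bins, columns=["chrom", "start", "arm"])
    samples = list(assignment)
    counts = np.empty((len(bframe), len(samples)), dtype=np.int64)
    truth_cn = {}
    arm_arr = bframe["arm"].to_numpy()
    for j, s in enumerate(samples):
        clone = assignment[s]
        cn = np.array([tree.clone_profile[clone][a] for a in arm_arr], dtype=float)
        counts[:, j] = rng.poisson(depth * cn / 2.0)
        truth_cn[s] = cn.astype(int)
    out = pd.concat(
        [bframe[["chrom", "start"]], pd.DataFrame(counts, columns=samples)], axis=1
    )
    truth = {
        "assignment": dict(assignment),
        "bin_cn": truth_cn,
        "bin_size": bin_size,
        "arm_events": sorted(truth_arm_events(tree, assignment)),
    }
    return out, truth


def sample_tree_newick(tree: CloneTree, assignment: dict[str, str]) -> str:
    """Ground-truth sample tree: clones as internal nodes, samples as leaves.

    Internal clone nodes with a single child chain are kept; zero-sample
    clones become plain internal nodes.  Useful as the truth topology when
    comparing against an inferred phylogeny.
    """
    children: dict[str, list[str]] = {c: [] for c in tree.clones}
    for c, p in tree.parent.items():
        if p is not None:
            children[p].append(c)
    by_clone: dict[str, list[str]] = {c: [] for c in tree.clones}
    for s, c in assignment.items():
        by_clone[c].append(s)

    def rec(clone: str) -> str:
        parts = sorted(by_clone[clone]) + [rec(ch) for ch in sorted(children[clone])]
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    return rec(ROOT_CLONE) + ";"


def dataclass_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["fish_params"] = {k: list(np.asarray(v, dtype=float)) for k, v in d["fish_params"].items()}
    return d
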