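"""Maximum-parsimony phylogenies and cluster support on arm-event characters.

Samples are coded as binary presence/absence of (arm, direction) events and
related by a rooted tree whose root is the all-neutral normal state.  Small
cohorts are solved exactly over all rooted leaf-labeled topologies; larger
ones use a deterministic heuristic (neighbor joining on Hamming distances
followed by nearest-neighbor-interchange hill climbing).  Cluster support
uses the approximately-unbiased (AU) p-value from multiscale bootstrap
resampling of characters; clusters with AU >= 0.95 count as strongly
supported.  Event statistics reproduce the per-group calling rule (event
present in >= 2 samples of a group), the shared/unique categorization, and
the recurrence threshold Q3 + 1.5 * IQR on event frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm

__all__ = [
    "Node",
    "PhyloTree",
    "ClusterSupport",
    "EventStats",
    "build_characters",
    "fitch_score",
    "parsimony_search",
    "hclust_au",
    "event_stats",
    "parse_newick",
    "robinson_foulds",
]

_BIG = 10**9
MAX_EXHAUSTIVE_LEAVES = 7


@dataclass
class Node:
    """Rooted (possibly multifurcating) tree node; leaves carry names."""

    name: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return self.name
        parts = sorted((c for c in self.children), key=lambda c: min(c.leaves()))
        return "(" + ",".join(p._nwk() for p in parts) + ")"


@dataclass
class PhyloTree:
    """Parsimony tree: root is the all-zero normal ancestor, leaves are
    samples; ``branch_events`` maps each clade (frozenset of leaf names) to
    the characters changing on the branch above it ('+' gained, '-' lost)."""

    root: Node
    score: int
    branch_events: dict[frozenset, list[str]]

    @property
    def newick(self) -> str:
        return self.root.newick()


def build_characters(arm_events: Iterable, samples: Sequence[str]) -> pd.DataFrame:
    """Binary character matrix samples x (arm, direction) events.

    ``arm_events`` yields objects with sample_id/arm/direction attributes
    (or (sample, arm, direction) tuples).  Characters constant zero across
    all samples are dropped; duplicate reports collapse to a single 1.
    """
    cols: dict[str, dict[str, int]] = {}
    for e in arm_events:
        if hasattr(e, "sample_id"):
            sample, arm, direction = e.sample_id, e.arm, e.direction
        else:
            sample, arm, direction = e
        if sample not in samples:
            continue
        cols.setdefault(f"{arm}:{direction}", {})[sample] = 1
    mat = pd.DataFrame(0, index=list(samples), columns=sorted(cols), dtype=int)
    for char, carriers in cols.items():
        for s in carriers:
            mat.loc[s, char] = 1
    return mat.loc[:, mat.sum(axis=0) > 0]


# ---------------------------------------------------------------------------
# small-parsimony scoring (Sankoff with unit costs, root fixed at all-zero)

def _tuple_cost(t, M: np.ndarray, idx: dict[str, int]) -> np.ndarray:
    """Min changes below node ``t`` for each (root state, character)."""
    if isinstance(t, str):
        row = M[idx[t]]
        cost = np.full((2, M.shape[1]), _BIG, dtype=np.int64)
        cost[0, row == 0] = 0
        cost[1, row == 1] = 0
        return cost
    total = np.zeros((2, M.shape[1]), dtype=np.int64)
    for child in t:
        c = _tuple_cost(child, M, idx)
        total[0] += np.minimum(c[0], c[1] + 1)
        total[1] += np.minimum(c[1], c[0] + 1)
    return total


def _node_to_tuple(node: Node):
    if node.is_leaf:
        return node.name
    return tuple(_node_to_tuple(c) for c in node.children)


def _as_tuple_tree(tree) :
    if isinstance(tree, Node):
        return _node_to_tuple(tree)
    return tree


def _score_vs_normal(cost: np.ndarray) -> int:
    """Total changes when the topology's root hangs off the all-zero normal
    ancestor by one branch (the root's own state is free)."""
    return int(np.minimum(cost[0], cost[1] + 1).sum())


def fitch_score(tree, matrix: pd.DataFrame) -> int:
    """Parsimony score of a rooted topology given binary characters.

    The tree descends from an implicit all-zero normal ancestor; the score
    is the minimal total number of character changes, including changes on
    the branch between the normal and the topology's root (exact also on
    multifurcating trees).  ``tree`` is a Node or nested tuple of leaf
    names matching the matrix index.
    """
    t = _as_tuple_tree(tree)
    leaves = _tuple_leaves(t)
    if set(leaves) != set(matrix.index) or len(leaves) != len(matrix.index):
        raise ValueError("tree leaves do not match matrix samples")
    if matrix.shape[1] == 0:
        return 0
    M = matrix.to_numpy()
    idx = {s: i for i, s in enumerate(matrix.index)}
    return _score_vs_normal(_tuple_cost(t, M, idx))


def _tuple_leaves(t) -> list[str]:
    if isinstance(t, str):
        return [t]
    return [x for c in t for x in _tuple_leaves(c)]


# ---------------------------------------------------------------------------
# topology enumeration and search

def _all_rooted_trees(leaves: Sequence[str]):
    """All rooted binary leaf-labeled topologies ((2n-3)!! of them)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    if len(leaves) == 2:
        yield (leaves[0], leaves[1])
        return
    first, rest = leaves[0], leaves[1:]
    base = first
    for t in _all_rooted_trees(rest):
        yield from _insert_everywhere(t, base)


def _insert_everywhere(t, x):
    yield (t, x)
    if not isinstance(t, str):
        a, b = t
        for sub in _insert_everywhere(a, x):
            yield (sub, b)
        for sub in _insert_everywhere(b, x):
            yield (a, sub)


def _canonical_newick(t) -> str:
    if isinstance(t, str):
        return t
    parts = sorted(_canonical_newick(c) for c in t)
    return "(" + ",".join(parts) + ")"


def _tuple_to_node(t) -> Node:
    if isinstance(t, str):
        return Node(name=t)
    return Node(children=[_tuple_to_node(c) for c in t])


def _prunings(t):
    """Yield (pruned subtree, remaining tree) for every prunable clade."""
    if isinstance(t, str):
        return
    a, b = t
    yield (a, b)
    yield (b, a)
    for s, rest in _prunings(a):
        yield (s, (rest, b))
    for s, rest in _prunings(b):
        yield (s, (a, rest))


def _spr_neighbors(t):
    """Subtree-prune-and-regraft neighborhood of a rooted binary tuple tree
    (deduplicated by canonical form; includes all NNI rearrangements)."""
    seen = {_canonical_newick(t)}
    for sub, rest in _prunings(t):
        for nb in _insert_everywhere(rest, sub):
            key = _canonical_newick(nb)
            if key not in seen:
                seen.add(key)
                yield nb


def _nj_start(matrix: pd.DataFrame):
    """Neighbor-joining start tree on Hamming distances, rooted at the
    attachment point of a pseudo-leaf carrying the all-zero normal state."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    samples = list(matrix.index)
    M = np.vstack([matrix.to_numpy(), np.zeros((1, matrix.shape[1]), dtype=int)])
    ids = samples + ["__normal__"]
    D = np.zeros((len(ids), len(ids)))
    for i, j in itertools.combinations(range(len(ids)), 2):
        d = int(np.sum(M[i] != M[j]))
        D[i, j] = D[j, i] = d
    sk = nj(DistanceMatrix(D, ids))
    sk = sk.root_at(sk.find("__normal__").parent)

    def convert(n) -> Node | None:
        if n.is_tip():
            return None if n.name == "__normal__" else Node(name=n.name)
        kids = [c for c in (convert(ch) for ch in n.children) if c is not None]
        if len(kids) == 1:
            return kids[0]
        return Node(children=kids)

    root = convert(sk)
    return _binarize(_node_to_tuple(root))


def _binarize(t):
    """Resolve multifurcations into left-leaning binary nodes (order-stable)."""
    if isinstance(t, str):
        return t
    kids = [_binarize(c) for c in t]
    while len(kids) > 2:
        kids = [(kids[0], kids[1])] + kids[2:]
    return tuple(kids) if len(kids) == 2 else kids[0]


def _spr_plateau_search(start, score, plateau_budget: int = 200):
    """Deterministic SPR hill climb with bounded plateau exploration.

    Strictly improving rearrangements are always taken (best neighbor,
    canonical-Newick tie-break).  On a plateau, up to ``plateau_budget``
    unvisited equal-score topologies are explored breadth-first before
    giving up — parsimony landscapes are full of score-flat ridges that
    plain hill climbing cannot cross.
    """
    best, best_score = start, score(start)
    start_key = _canonical_newick(start)
    visited = {start_key}
    frontier = [(start_key, start)]
    while True:
        # strict improvement pass from the current best
        cand = []
        for key, t in frontier:
            for nb in _spr_neighbors(t):
                k = _canonical_newick(nb)
                if k in visited:
                    continue
                s = score(nb)
                if s < best_score:
                    cand.append((s, k, nb))
        if cand:
            best_score, key, best = min(cand, key=lambda c: (c[0], c[1]))
            visited = {key}
            frontier = [(key, best)]
            continue
        # plateau: collect equal-score unvisited neighbors breadth-first
        plateau = []
        for key, t in frontier:
            for nb in _spr_neighbors(t):
                k = _canonical_newick(nb)
                if k not in visited and score(nb) == best_score:
                    visited.add(k)
                    plateau.append((k, nb))
        plateau.sort(key=lambda p: p[0])
        plateau = plateau[: max(plateau_budget - len(visited), 0)]
        if not plateau or len(visited) >= plateau_budget:
            return best, best_score
        frontier = plateau


def parsimony_search(matrix: pd.DataFrame, mode: str = "auto") -> PhyloTree:
    """Find a maximum-parsimony rooted tree for the character matrix.

    ``exhaustive`` scores every rooted leaf-labeled binary topology (global
    optimum; limited to 7 leaves); ``heuristic`` starts from a
    neighbor-joining tree on Hamming distances (with the normal root as a
    pseudo-leaf) and hill-climbs over the subtree-prune-and-regraft
    neighborhood until no rearrangement improves the score.  Both are
    deterministic and seed-free: score ties break on the canonical Newick
    string.  Internal branches carrying no character change are collapsed,
    so identical samples form polytomies.
    """
    samples = list(matrix.index)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if mode not in ("auto", "exhaustive", "heuristic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exhaustive" and len(samples) > MAX_EXHAUSTIVE_LEAVES:
        raise ValueError(
            f"exhaustive search is limited to {MAX_EXHAUSTIVE_LEAVES} leaves; use mode='heuristic'"
        )
    if mode == "auto":
        mode = "exhaustive" if len(samples) <= MAX_EXHAUSTIVE_LEAVES else "heuristic"

    M = matrix.to_numpy()
    idx = {s: i for i, s in enumerate(samples)}

    def score(t) -> int:
        if matrix.shape[1] == 0:
            return 0
        return _score_vs_normal(_tuple_cost(t, M, idx))

    if mode == "exhaustive":
        best, best_key, best_score = None, None, None
        for t in _all_rooted_trees(samples):
            s = score(t)
            key = _canonical_newick(t)
            if best_score is None or s < best_score or (s == best_score and key < best_key):
                best, best_key, best_score = t, key, s
    else:
        if len(samples) == 2:
            best = (samples[0], samples[1])
        else:
            best = _nj_start(matrix)
        best, best_score = _spr_plateau_search(best, score)
    return _finalize_tree(best, matrix, best_score)


def _finalize_tree(t, matrix: pd.DataFrame, score: int) -> PhyloTree:
    root = _tuple_to_node(t)
    states: dict[int, np.ndarray] = {}
    if matrix.shape[1] == 0:
        # no characters: every branch is change-free, collapse to a star
        star = Node(children=[Node(name=s) for s in matrix.index])
        return PhyloTree(root=star, score=0, branch_events={})
    M = matrix.to_numpy()
    idx = {s: i for i, s in enumerate(matrix.index)}

    costs: dict[int, np.ndarray] = {}

    def up(node: Node) -> np.ndarray:
        if node.is_leaf:
            row = M[idx[node.name]]
            c = np.full((2, M.shape[1]), _BIG, dtype=np.int64)
            c[0, row == 0] = 0
            c[1, row == 1] = 0
        else:
            c = np.zeros((2, M.shape[1]), dtype=np.int64)
            for ch in node.children:
                cc = up(ch)
                c[0] += np.minimum(cc[0], cc[1] + 1)
                c[1] += np.minimum(cc[1], cc[0] + 1)
        costs[id(node)] = c
        return c

    up(root)

    def down(node: Node, parent_state: np.ndarray):
        c = costs[id(node)]
        stay = c[parent_state, np.arange(M.shape[1])]
        flip = c[1 - parent_state, np.arange(M.shape[1])] + 1
        state = np.where(flip < stay, 1 - parent_state, parent_state)
        states[id(node)] = state
        for ch in node.children:
            down(ch, state)

    # the topology root hangs off the all-zero normal: its state minimizes
    # subtree cost plus one change if it differs from normal (ties -> 0)
    c_root = costs[id(root)]
    root_state = (c_root[1] + 1 < c_root[0]).astype(np.int64)
    states[id(root)] = root_state
    for ch in root.children:
        down(ch, root_state)

    # collapse change-free internal branches (keeps leaves, keeps the root)
    def collapse(node: Node):
        new_children = []
        for ch in node.children:
            collapse(ch)
            if not ch.is_leaf and np.array_equal(states[id(ch)], states[id(node)]):
                new_children.extend(ch.children)
            else:
                new_children.append(ch)
        node.children = new_children

    collapse(root)

    branch_events: dict[frozenset, list[str]] = {}
    chars = list(matrix.columns)

    def record(node: Node, parent_state: np.ndarray):
        st = states[id(node)]
        changes = [
            chars[k] + ("+" if st[k] == 1 else "-")
            for k in range(len(chars))
            if st[k] != parent_state[k]
        ]
        if changes:
            branch_events[frozenset(node.leaves())] = changes
        for ch in node.children:
            record(ch, st)

    record(root, np.zeros(M.shape[1], dtype=np.int64))
    return PhyloTree(root=root, score=score, branch_events=branch_events)


# ---------------------------------------------------------------------------
# newick parsing and Robinson-Foulds distance

def parse_newick(s: str) -> Node:
    """Parse a plain Newick string (names, optional lengths ignored)."""
    s = s.strip().rstrip(";")
    pos = 0

    def parse() -> Node:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")", f"unbalanced newick at {pos}"
            pos += 1
            name = _read_label()
            node = Node(children=children)
            if name:
                node.name = name
            return node
        name = _read_label()
        return Node(name=name)

    def _read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",();:":
            pos += 1
        label = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
        return label

    return parse()


def _splits(tree) -> set[frozenset]:
    root = tree.root if isinstance(tree, PhyloTree) else tree
    if isinstance(root, str):
        root = parse_newick(root)
    all_leaves = frozenset(root.leaves())
    out: set[frozenset] = set()

    def rec(node: Node):
        for ch in node.children:
            clade = frozenset(ch.leaves())
            if 1 < len(clade) < len(all_leaves) - 1:
                out.add(frozenset({clade, all_leaves - clade}))
            rec(ch)

    rec(root)
    return out


def robinson_foulds(a, b) -> int:
    """Unrooted Robinson-Foulds distance between two trees (Node, PhyloTree,
    or Newick string) on the same leaf set."""
    ra = a.root if isinstance(a, PhyloTree) else (parse_newick(a) if isinstance(a, str) else a)
    rb = b.root if isinstance(b, PhyloTree) else (parse_newick(b) if isinstance(b, str) else b)
    if set(ra.leaves()) != set(rb.leaves()):
        raise ValueError("trees have different leaf sets")
    sa, sb = _splits(ra), _splits(rb)
    return len(sa ^ sb)


# ---------------------------------------------------------------------------
# multiscale bootstrap (AU) cluster support

@dataclass
class ClusterSupport:
    """Average-linkage dendrogram with AU/BP support per internal cluster."""

    linkage_matrix: np.ndarray
    samples: list[str]
    clusters: list[frozenset]
    au: np.ndarray
    bp: np.ndarray
    table: pd.DataFrame
    settings: dict


def _linkage_clusters(Z: np.ndarray, n: int) -> list[frozenset]:
    sets: list[frozenset] = [frozenset([i]) for i in range(n)]
    out = []
    for row in Z:
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets.append(merged)
        out.append(merged)
    return out


def hclust_au(
    data: pd.DataFrame,
    B: int = 1000,
    scales: Sequence[float] = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2)),
    seed: int = 0,
) -> ClusterSupport:
    """Approximately-unbiased cluster support via multiscale bootstrap.

    Builds the average-linkage Euclidean dendrogram of ``data`` (samples x
    features), then for each scale r draws B bootstrap resamples of
    round(r * n_features) feature columns, recomputes the dendrogram, and
    records per observed cluster the fraction BP_r of resamples containing
    it.  The signed-distance fit z_r = Phi^-1(1 - BP_r) = v sqrt(r) +
    c / sqrt(r) over scales with 0 < BP_r < 1 gives AU = 1 - Phi(v - c).
    Clusters with BP 0 (or 1) at every scale get AU 0 (or 1).

    Columns are sorted into a canonical order before resampling, so the
    result is exactly invariant under column permutation of the input
    (features are exchangeable in a bootstrap of features).
    """
    if len(data) < 3:
        raise ValueError("need at least three samples")
    if B < 100:
        raise ValueError("B must be at least 100")
    X = data.to_numpy(dtype=float)
    X = X[:, np.lexsort(X[::-1])]
    n, p = X.shape
    Z = linkage(pdist(X), method="average")
    clusters = _linkage_clusters(Z, n)
    observed = {c: k for k, c in enumerate(clusters)}

    rng = np.random.default_rng(seed)
    scales = list(scales)
    bp = np.zeros((len(scales), len(clusters)))
    for si, r in enumerate(scales):
        m = max(2, int(round(r * p)))
        hits = np.zeros(len(clusters))
        for _ in range(B):
            cols = rng.integers(0, p, size=m)
            Zb = linkage(pdist(X[:, cols]), method="average")
            for c in _linkage_clusters(Zb, n):
                k = observed.get(c)
                if k is not None:
                    hits[k] += 1
        bp[si] = hits / B

    au = np.zeros(len(clusters))
    degenerate = np.zeros(len(clusters), dtype=bool)
    sq = np.sqrt(np.asarray(scales))
    for k in range(len(clusters)):
        usable = (bp[:, k] > 0) & (bp[:, k] < 1)
        if usable.sum() < 2:
            au[k] = 1.0 if bp[:, k].mean() >= 0.5 else 0.0
            degenerate[k] = True
            continue
        z = norm.ppf(1 - bp[usable, k])
        A = np.column_stack([sq[usable], 1 / sq[usable]])
        (v, c), *_ = np.linalg.lstsq(A, z, rcond=None)
        au[k] = float(1 - norm.cdf(v - c))
    bp1 = bp[scales.index(1.0)] if 1.0 in scales else bp[np.argmin(np.abs(np.asarray(scales) - 1))]
    table = pd.DataFrame(
        {
            "cluster": [" ".join(sorted(data.index[list(c)])) for c in clusters],
            "size": [len(c) for c in clusters],
            "au": au,
            "bp": bp1,
            "degenerate": degenerate,
            "supported": au >= 0.95,
        }
    )
    return ClusterSupport(
        linkage_matrix=Z,
        samples=list(data.index),
        clusters=clusters,
        au=au,
        bp=bp1,
        table=table,
        settings={"B": B, "scales": scales, "seed": seed},
    )


# ---------------------------------------------------------------------------
# event statistics

@dataclass
class EventStats:
    group_events: dict[str, set]
    categories: dict[tuple, str]
    category_percent: dict[str, float]
    frequencies: pd.DataFrame  # events x groups, fraction of group's samples
    thresholds: dict[str, float]
    recurrent: dict[str, list]


def event_stats(
    arm_events: Iterable,
    groups: dict[str, str],
    min_samples: int = 2,
    amp_group: str = "DCIS_amp",
    noamp_group: str = "DCIS_noamp",
) -> EventStats:
    """Per-group CNV calling, shared/unique categorization, and recurrence.

    An event (arm, direction) is called for a group when it is detected in
    at least ``min_samples`` of the group's samples.  Called events of the
    amp/noamp pair are categorized shared / unique_amp / unique_noamp (as
    percentages of their union).  Per group, each called event's frequency
    is the fraction of the group's samples carrying it; events above the
    upper Tukey fence Q3 + 1.5*IQR of the group's frequency vector are
    flagged recurrent.
    """
    carriers: dict[tuple, set] = {}
    for e in arm_events:
        if hasattr(e, "sample_id"):
            sample, arm, direction = e.sample_id, e.arm, e.direction
        else:
            sample, arm, direction = e
        if sample in groups:
            carriers.setdefault((arm, direction), set()).add(sample)
    group_names = sorted(set(groups.values()))
    members = {g: {s for s, gg in groups.items() if gg == g} for g in group_names}

    group_events: dict[str, set] = {}
    for g in group_names:
        if len(members[g]) < min_samples:
            import warnings

            warnings.warn(f"group {g} has fewer than {min_samples} samples; no events called")
            group_events[g] = set()
            continue
        group_events[g] = {
            ev for ev, ss in carriers.items() if len(ss & members[g]) >= min_samples
        }

    amp_set = group_events.get(amp_group, set())
    noamp_set = group_events.get(noamp_group, set())
    union = amp_set | noamp_set
    categories = {}
    for ev in union:
        if ev in amp_set and ev in noamp_set:
            categories[ev] = "shared"
        elif ev in amp_set:
            categories[ev] = "unique_amp"
        else:
            categories[ev] = "unique_noamp"
    n_union = max(len(union), 1)
    category_percent = {
        cat: 100.0 * sum(1 for v in categories.values() if v == cat) / n_union
        for cat in ("shared", "unique_amp", "unique_noamp")
    }

    freq_rows = {}
    for g in group_names:
        for ev in group_events[g]:
            freq_rows.setdefault(ev, {})[g] = len(carriers[ev] & members[g]) / len(members[g])
    frequencies = pd.DataFrame(freq_rows).T if freq_rows else pd.DataFrame(columns=group_names)
    frequencies = frequencies.reindex(columns=group_names)

    thresholds, recurrent = {}, {}
    for g in group_names:
        freqs = frequencies[g].dropna().to_numpy() if g in frequencies else np.array([])
        if len(freqs) == 0:
            thresholds[g] = float("nan")
            recurrent[g] = []
            continue
        q3, q1 = np.quantile(freqs, [0.75, 0.25])
        t = q3 + 1.5 * (q3 - q1)
        thresholds[g] = float(t)
        recurrent[g] = sorted(
            ev for ev in group_events[g] if frequencies.loc[[ev], g].iloc[0] > t
        )
    return EventStats(
        group_events=group_events,
        categories=categories,
        category_percent=category_percent,
        frequencies=frequencies,
        thresholds=thresholds,
        recurrent=recurrent,
    )
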