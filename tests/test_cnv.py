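"""Log2 ratio profiles, joint segmentation, state calling, filtering, arm
events, the noise consensus, block aggregation, and cross-platform checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ductevo.cnv import (
    ArmEvent,
    BinProfiles,
    CNV_CUTOFFS,
    Segment,
    call_states,
    chr17_blocks,
    cross_platform_correlation,
    expression_pipeline,
    expression_to_bins,
    filter_and_merge,
    multisample_segment,
    noise_consensus,
    segments_to_arm_events,
    wgs_to_bins,
)
from ductevo.synthetic import (
    CloneTree,
    SimulationConfig,
    assign_samples,
    make_clone_tree,
    make_genome,
    simulate_expression,
    simulate_wgs_bins,
)


def _toy_annotation(n, chrom="chr1", spacing=1_000_000):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "tts": np.arange(n) * spacing,
        }
    )


class TestExpressionToBins:
    def test_sample_equal_to_normals_is_zero(self):
        ann = _toy_annotation(50)
        counts = pd.DataFrame(
            {s: np.full(50, 100) for s in ("n1", "n2", "t1")},
            index=ann["gene_id"],
        )
        prof = expression_to_bins(counts, ann, ["n1", "n2"])
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_doubled_arm_close_to_plus_one(self, rng):
        ann = _toy_annotation(400)
        base = rng.integers(500, 2000, 400).astype(float)
        tumor = base.copy()
        tumor[:100] *= 2  # first quarter of the loci doubled
        counts = pd.DataFrame({"n1": base, "n2": base, "t1": tumor}, index=ann["gene_id"])
        prof = expression_to_bins(counts, ann, ["n1", "n2"])
        j = prof.samples.index("t1")
        doubled = prof.values[:100, j]
        # cpm renormalization and median centering shift the ratio a little
        assert abs(np.median(doubled) - 1.0) < 0.1

    def test_gained_arm_median_near_log2_1_5(self, genome, default_config):
        arms = list(genome.arms()["arm"])
        prof3 = {a: 2 for a in arms}
        prof3["1q"] = 3
        tree = CloneTree(
            {"normal": None, "c": "normal"},
            {"c": [("1q", "gain")]},
            {"normal": {a: 2 for a in arms}, "c": prof3},
        )
        asg = {"n1": "normal", "n2": "normal", "n3": "normal", "n4": "normal", "t1": "c"}
        counts, _ = simulate_expression(genome, tree, default_config, asg)
        prof = expression_to_bins(counts, genome.genes, ["n1", "n2", "n3", "n4"])
        j = prof.samples.index("t1")
        arm_ids = set(genome.genes.loc[genome.genes["arm"] == "1q", "gene_id"])
        mask = prof.loci["id"].isin(arm_ids).to_numpy()
        assert abs(np.median(prof.values[mask, j]) - np.log2(1.5)) < 0.15

    def test_requires_normals(self):
        ann = _toy_annotation(10)
        counts = pd.DataFrame({"t1": np.ones(10)}, index=ann["gene_id"])
        with pytest.raises(ValueError):
            expression_to_bins(counts, ann, [])

    def test_unannotated_gene_dropped_with_warning(self):
        ann = _toy_annotation(10)
        counts = pd.DataFrame(
            {"n1": np.ones(11), "t1": np.ones(11)},
            index=list(ann["gene_id"]) + ["mystery"],
        )
        with pytest.warns(UserWarning):
            prof = expression_to_bins(counts, ann, ["n1"])
        assert "mystery" not in set(prof.loci["id"])


class TestWgsToBins:
    def test_neutral_genome_median_zero(self, genome, default_config):
        arms = genome.arms()["arm"]
        tree = CloneTree({"normal": None}, {}, {"normal": {a: 2 for a in arms}})
        bins, _ = simulate_wgs_bins(
            genome, tree, default_config, {"n1": "normal", "t1": "normal"}, depth=20
        )
        prof = wgs_to_bins(bins, ["n1"])
        j = prof.samples.index("t1")
        assert abs(np.median(prof.values[:, j])) < 0.05

    def test_cn4_arm_median_near_one(self, genome, default_config):
        arms = list(genome.arms()["arm"])
        prof4 = {a: 2 for a in arms}
        prof4["2q"] = 4
        tree = CloneTree(
            {"normal": None, "c": "normal"},
            {"c": [("2q", "gain"), ("2q", "gain")]},
            {"normal": {a: 2 for a in arms}, "c": prof4},
        )
        bins, _ = simulate_wgs_bins(
            genome, tree, default_config, {"n1": "normal", "t1": "c"}, depth=50
        )
        p = wgs_to_bins(bins, ["n1"])
        j = p.samples.index("t1")
        cent = int(genome.chromosomes.set_index("chrom").loc["chr2", "centromere"])
        mask = ((p.loci["chrom"] == "chr2") & (p.loci["pos"] >= cent)).to_numpy()
        assert abs(np.median(p.values[mask, j]) - 1.0) < 0.1

    def test_empty_normal_set_rejected(self):
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "t1": [5]})
        with pytest.raises(ValueError):
            wgs_to_bins(bins, [])


def _profiles_from_array(x, spacing=1_000_000, chrom="chr1"):
    n = x.shape[0]
    loci = pd.DataFrame(
        {"id": [f"g{i}" for i in range(n)], "chrom": chrom, "pos": np.arange(n) * spacing}
    )
    return BinProfiles(
        loci=loci, values=np.asarray(x, dtype=float), samples=[f"s{j}" for j in range(x.shape[1])],
        source="expression",
    )


def _brute_force_cost(x, gamma):
    """Exhaustive minimum of SSE + gamma * breakpoints over all segmentations."""
    n = x.shape[0]
    best = np.inf
    for mask in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, b in enumerate(mask) if b] + [n]
        cost = gamma * (len(bounds) - 2)
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x[a:b]
            cost += ((seg - seg.mean(axis=0)) ** 2).sum()
        best = min(best, cost)
    return best


class TestMultisampleSegment:
    def test_noiseless_shared_jump_recovered(self):
        x = np.zeros((40, 2))
        x[20:] = 1.0
        prof = _profiles_from_array(x)
        bps, segs = multisample_segment(prof, gamma=1.0, recenter=False)
        assert bps["chr1"] == [20]

    def test_huge_penalty_gives_single_segment(self, rng):
        x = rng.normal(size=(60, 2))
        prof = _profiles_from_array(x)
        bps, segs = multisample_segment(prof, gamma=1e9)
        assert bps["chr1"] == []
        assert len({(s.start, s.end) for s in segs}) == 1

    def test_dp_matches_exhaustive_enumeration(self, rng):
        for rep in range(20):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, k)) + rng.choice([0, 1.5], size=(n, 1))
            gamma = float(rng.uniform(0.5, 6.0))
            prof = _profiles_from_array(x)
            bps, segs = multisample_segment(prof, gamma=gamma, min_seg=1, recenter=False)
            bounds = [0] + bps["chr1"] + [n]
            dp_cost = gamma * len(bps["chr1"]) + sum(
                ((x[a:b] - x[a:b].mean(axis=0)) ** 2).sum()
                for a, b in zip(bounds[:-1], bounds[1:])
            )
            assert dp_cost == pytest.approx(_brute_force_cost(x, gamma), rel=1e-9)

    def test_breakpoints_shared_across_samples(self, patient, genome):
        prof = expression_to_bins(patient["counts"], genome.genes, patient["normals"])
        _, segs = multisample_segment(prof, chrom_sizes=genome.chrom_sizes())
        per_sample = {}
        for s in segs:
            per_sample.setdefault(s.sample_id, []).append((s.chrom, s.start, s.end))
        layouts = {tuple(sorted(v)) for v in per_sample.values()}
        assert len(layouts) == 1

    def test_fewer_loci_than_min_seg_single_segment(self):
        prof = _profiles_from_array(np.ones((3, 2)))
        bps, segs = multisample_segment(prof, gamma=1.0, min_seg=5)
        assert bps["chr1"] == []


class TestCallStates:
    @pytest.mark.parametrize(
        "mean_log2,state",
        [
            (-0.50, "deletion"),
            (0.0, "neutral"),
            (0.25, "gain"),
            (0.50, "amplification"),
            (-0.30, "loss"),
            # exactly at a cutoff -> less extreme state
            (CNV_CUTOFFS["deletion"], "loss"),
            (CNV_CUTOFFS["loss"], "neutral"),
            (CNV_CUTOFFS["gain"], "neutral"),
            (CNV_CUTOFFS["amplification"], "gain"),
        ],
    )
    def test_cutoff_ladder(self, mean_log2, state):
        (seg,) = call_states(
            [Segment("s", "chr1", 0, 10_000_000, 10, mean_log2)]
        )
        assert seg.state == state

    def test_monotone_in_mean(self, rng):
        order = ["deletion", "loss", "neutral", "gain", "amplification"]
        means = sorted(rng.uniform(-1, 1, 50))
        states = [
            call_states([Segment("s", "chr1", 0, 1, 1, m)])[0].state for m in means
        ]
        ranks = [order.index(s) for s in states]
        assert ranks == sorted(ranks)


class TestFilterAndMerge:
    def _segs(self, gain_len):
        return call_states(
            [
                Segment("s", "chr1", 0, 30_000_000, 30, 0.0),
                Segment("s", "chr1", 30_000_000, 30_000_000 + gain_len, 10, 0.25),
                Segment("s", "chr1", 30_000_000 + gain_len, 90_000_000, 30, 0.0),
            ]
        )

    def test_focal_gain_below_10mb_removed_and_merged(self):
        out = filter_and_merge(self._segs(9_900_000))
        assert len(out) == 1 and out[0].state == "neutral"
        assert (out[0].start, out[0].end) == (0, 90_000_000)

    def test_gain_at_exactly_10mb_retained(self):
        out = filter_and_merge(self._segs(10_000_000))
        assert [s.state for s in out] == ["neutral", "gain", "neutral"]

    def test_same_state_neighbors_merge_locus_weighted(self):
        segs = call_states(
            [
                Segment("s", "chr1", 0, 20_000_000, 10, 0.4),
                Segment("s", "chr1", 20_000_000, 60_000_000, 30, 0.6),
            ]
        )
        (merged,) = filter_and_merge(segs)
        assert merged.n_loci == 40
        assert merged.mean_log2 == pytest.approx((0.4 * 10 + 0.6 * 30) / 40)

    def test_idempotent(self, rng):
        segs = call_states(
            [
                Segment(
                    "s",
                    "chr1",
                    i * 12_000_000,
                    (i + 1) * 12_000_000,
                    12,
                    float(rng.uniform(-0.6, 0.6)),
                )
                for i in range(8)
            ]
        )
        once = filter_and_merge(segs)
        twice = filter_and_merge(once)
        assert once == twice


class TestArmEvents:
    def _arms(self):
        return pd.DataFrame(
            [("1p", "chr1", 0, 40_000_000), ("1q", "chr1", 40_000_000, 100_000_000)],
            columns=["arm", "chrom", "start", "end"],
        )

    def test_whole_arm_gain_full_coverage(self):
        segs = call_states([Segment("s", "chr1", 0, 100_000_000, 50, 0.5)])
        events = segments_to_arm_events(segs, self._arms(), chromosomes=None)
        assert {(e.arm, e.direction, e.covered_fraction) for e in events} == {
            ("1p", "gain", 1.0),
            ("1q", "gain", 1.0),
        }

    def test_partial_coverage_below_threshold_no_event(self):
        segs = call_states(
            [
                Segment("s", "chr1", 40_000_000, 64_000_000, 10, 0.5),  # 40% of 1q
                Segment("s", "chr1", 64_000_000, 100_000_000, 20, 0.0),
            ]
        )
        events = segments_to_arm_events(segs, self._arms(), chromosomes=None)
        assert events == []

    def test_chromosome_restriction_excludes_chr16(self):
        arms = pd.DataFrame(
            [("16p", "chr16", 0, 40_000_000)], columns=["arm", "chrom", "start", "end"]
        )
        segs = call_states([Segment("s", "chr16", 0, 40_000_000, 20, 0.6)])
        assert segments_to_arm_events(segs, arms) == []
        assert len(segments_to_arm_events(segs, arms, chromosomes=None)) == 1


class TestNoiseConsensus:
    def test_recovery_with_consensus(self, genome, clone_tree, default_config, patient):
        cons, report = noise_consensus(
            patient["counts"],
            genome.genes,
            patient["normals"],
            genome.arms(),
            genome.chrom_sizes(),
            seeds=(101, 102),
            chromosomes=None,
        )
        pred = {(e.sample_id, e.arm, e.direction) for e in cons}
        truth = set(map(tuple, patient["truth"]["arm_events"]))
        tp = len(pred & truth)
        assert tp / len(truth) >= 0.9
        assert tp / len(pred) >= 0.9
        # every consensus event appears in at least 2 of the 3 runs
        runs = [set(r) for r in report["runs"]]
        for key in report["consensus"]:
            assert sum(key in r for r in runs) >= 2

    def test_null_patient_keeps_consensus_below_raw(self, genome, default_config):
        arms = genome.arms()["arm"]
        tree = CloneTree({"normal": None}, {}, {"normal": {a: 2 for a in arms}})
        asg = {f"n{i}": "normal" for i in range(8)}
        counts, _ = simulate_expression(genome, tree, default_config, asg)
        normals = list(asg)[:3]
        _, raw = expression_pipeline(
            counts, genome.genes, normals, genome.arms(), genome.chrom_sizes(), chromosomes=None
        )
        cons, _ = noise_consensus(
            counts, genome.genes, normals, genome.arms(), genome.chrom_sizes(),
            seeds=(7, 8), chromosomes=None,
        )
        assert len(cons) <= len(raw)
        assert len(cons) <= 1


class TestChr17Blocks:
    def test_normal_sample_blocks_near_zero(self, rng):
        ann = _toy_annotation(100, spacing=200_000)
        base = rng.integers(200, 800, 100).astype(float)
        counts = pd.DataFrame({"n1": base, "n2": base, "t1": base}, index=ann["gene_id"])
        bm = chr17_blocks(counts, ann, ["n1", "n2"], chrom="chr1")
        np.testing.assert_allclose(bm["t1"], 0.0, atol=1e-9)

    def test_half_open_block_boundary(self):
        ann = pd.DataFrame(
            {"gene_id": ["a", "b"], "chrom": ["chr1"] * 2, "tts": [499_999, 500_000]}
        )
        counts = pd.DataFrame({"n1": [10, 10], "t1": [10, 10]}, index=["a", "b"])
        bm = chr17_blocks(counts, ann, ["n1"], chrom="chr1")
        assert list(bm.index) == [0, 500_000]

    def test_designed_amplicon_elevates_exact_blocks(self, rng):
        n = 200
        tts = np.sort(rng.choice(20_000_000, n, replace=False))
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], "chrom": "chr1", "tts": tts})
        block = tts // 500_000
        amp = (block >= 10) & (block <= 14)
        base = rng.lognormal(3, 1, n)
        cols = {}
        for j, s in enumerate(["n1", "n2", "n3", "t1", "t2"]):
            mu = base.copy()
            if s.startswith("t"):
                mu[amp] *= 8
            cols[s] = rng.poisson(mu * 50)
        counts = pd.DataFrame(cols, index=ann["gene_id"])
        bm = chr17_blocks(counts, ann, ["n1", "n2", "n3"], chrom="chr1")
        elevated = set(bm.index[bm["t1"] > 1.5]) | set(bm.index[bm["t2"] > 1.5])
        assert elevated == set(block[amp] * 500_000)

    def test_no_genes_on_chromosome_warns(self):
        ann = _toy_annotation(5)
        counts = pd.DataFrame({"n1": np.ones(5)}, index=ann["gene_id"])
        with pytest.warns(UserWarning):
            bm = chr17_blocks(counts, ann, ["n1"], chrom="chr99")
        assert bm.empty


class TestCrossPlatform:
    def _segs(self, sample, means):
        return call_states(
            [
                Segment(sample, "chr1", i * 20_000_000, (i + 1) * 20_000_000, 20, m)
                for i, m in enumerate(means)
            ]
        )

    def test_identical_segments_correlate_perfectly(self):
        ann = _toy_annotation(100)
        se = self._segs("s1", [0.0, 0.5, -0.4, 0.2, -0.1])
        rho = cross_platform_correlation(se, se, ann, chromosomes=None)
        assert rho["s1"] == pytest.approx(1.0)

    def test_negated_segments_anticorrelate(self):
        ann = _toy_annotation(100)
        se = self._segs("s1", [0.1, 0.5, -0.4, 0.2, -0.1])
        sw = self._segs("s1", [-0.1, -0.5, 0.4, -0.2, 0.1])
        rho = cross_platform_correlation(se, sw, ann, chromosomes=None)
        assert rho["s1"] == pytest.approx(-1.0)

    def test_too_few_shared_genes_missing(self):
        ann = _toy_annotation(5)
        se = self._segs("s1", [0.0])
        rho = cross_platform_correlation(se, se, ann, chromosomes=None, min_genes=10)
        assert np.isnan(rho["s1"])

    def test_paired_simulation_agrees(self):
        cfg = SimulationConfig(seed=0, n_chromosomes=5, genes_per_chromosome=150)
        g = make_genome(cfg)
        t = make_clone_tree(cfg, n_clones=2, n_events=5, genome=g)
        asg = assign_samples(t, 3)
        counts, _ = simulate_expression(g, t, cfg, asg)
        wgs, _ = simulate_wgs_bins(g, t, cfg, asg, depth=10)
        normals = [s for s, c in asg.items() if c == "normal"]
        pe = expression_to_bins(counts, g.genes, normals)
        _, se = multisample_segment(pe, chrom_sizes=g.chrom_sizes())
        pw = wgs_to_bins(wgs, normals)
        _, sw = multisample_segment(pw, chrom_sizes=g.chrom_sizes())
        rho = cross_platform_correlation(
            call_states(se), call_states(sw), g.genes, chromosomes=None
        )
        tumor = [s for s, c in asg.items() if c != "normal"]
        assert (rho[tumor] > 0.5).all()
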