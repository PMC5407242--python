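"""Overlap graph: backbones, step rules, rollback and full refinement."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pseudomap.anchor import (
    ANCHORED,
    INCONSISTENT,
    UNANCHORED,
    BacAnchor,
    MapPosition,
    anchor_all_bacs,
    rescue_via_neighbors,
)
from pseudomap.graph import (
    BacMeta,
    Candidate,
    OverlapGraph,
    RefinementEvidence,
    add_edges_with_rollback,
    build_initial_graph,
    compute_backbone,
    meta_from_library,
    om_best_alignments,
    run_refinement,
)
from pseudomap.overlaps import OverlapCall, compute_overlaps
from tests.conftest import clean_config


def simple_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestBackbone:
    def test_path_graph_diameter_and_ranks(self):
        bb = compute_backbone(simple_graph([("a", "b", 1), ("b", "c", 1)]))
        assert bb.diameter == ["a", "b", "c"]
        assert all(r == 0 for r in bb.rank.values())
        assert not bb.branched

    def test_star_leaves_one_rank1_node(self):
        g = simple_graph(
            [("x", "a", 1), ("x", "b", 1), ("x", "c", 1)]
        )
        bb = compute_backbone(g)
        assert len(bb.diameter) == 3
        off = set(g.nodes) - set(bb.diameter)
        assert len(off) == 1
        assert bb.rank[off.pop()] == 1
        assert not bb.branched

    def test_rank2_node_means_branched(self):
        # long spine a..h with a two-node branch x-y hanging off d: the
        # diameter stays on the spine, so y sits at rank 2
        spine = list("abcdefgh")
        edges = [(u, v, 1) for u, v in zip(spine[:-1], spine[1:])]
        edges += [("d", "x", 1), ("x", "y", 1)]
        bb = compute_backbone(simple_graph(edges))
        assert bb.diameter == spine
        assert bb.rank["x"] == 1 and bb.rank["y"] == 2
        assert bb.branched
        assert set(bb.branch_nodes()) == {"x", "y"}

    def test_mst_keeps_heaviest_overlaps(self):
        # triangle: the lightest edge (a-c) must be dropped
        g = simple_graph([("a", "b", 10), ("b", "c", 9), ("a", "c", 1)])
        bb = compute_backbone(g)
        assert set(map(frozenset, bb.mst.edges)) == {
            frozenset({"a", "b"}), frozenset({"b", "c"})
        }

    def test_disconnected_input_raises(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1)
        g.add_node("z")
        with pytest.raises(ValueError, match="disconnected"):
            compute_backbone(g)

    def test_mst_weight_matches_exhaustive_search(self, rng):
        """Random sparse graphs up to 12 nodes: the Prim MST (on negated
        overlap weights) equals the best spanning tree found by exhaustive
        enumeration of edge subsets."""
        for trial in range(30):
            n = int(rng.integers(4, 13))
            nodes = [f"n{i}" for i in range(n)]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            # random spanning tree plus a few extra edges
            for i in range(1, n):
                j = int(rng.integers(0, i))
                g.add_edge(nodes[i], nodes[j],
                           weight=float(rng.integers(1, 100)))
            extra = min(4, n * (n - 1) // 2 - (n - 1))
            while extra > 0:
                u, v = rng.choice(n, 2, replace=False)
                if not g.has_edge(nodes[u], nodes[v]):
                    g.add_edge(nodes[u], nodes[v],
                               weight=float(rng.integers(1, 100)))
                    extra -= 1
            bb = compute_backbone(g)
            got = sum(g[u][v]["weight"] for u, v in bb.mst.edges)
            best = -np.inf
            edges = list(g.edges(data="weight"))
            for subset in itertools.combinations(edges, n - 1):
                t = nx.Graph()
                t.add_nodes_from(nodes)
                t.add_weighted_edges_from(subset)
                if nx.is_connected(t):
                    best = max(best, sum(w for _, _, w in subset))
            assert got == pytest.approx(best)


def make_meta(bacs, length=100_000, fp="fp1", mtp=True):
    return {
        b: BacMeta(b, length, 30_000, mtp, False, fp, float(i))
        for i, b in enumerate(bacs)
    }


def make_anchors(bacs, chrom="chr1", cms=None):
    cms = cms or {b: 10.0 for b in bacs}
    return {
        b: BacAnchor(b, ANCHORED, MapPosition(chrom, cms[b])) for b in bacs
    }


class TestInitialGraph:
    def test_different_fp_contigs_draw_no_edge(self):
        meta = make_meta(["a"], fp="fp1") | make_meta(["b"], fp="fp2")
        calls = [OverlapCall("a", "b", "permissive", 20_000, 20_000)]
        og = build_initial_graph(meta, calls, make_anchors(["a", "b"]))
        assert og.g.number_of_edges() == 0

    def test_extent_below_5pct_draws_no_edge(self):
        meta = make_meta(["a", "b"])
        calls = [OverlapCall("a", "b", "permissive", 4_000, 4_000)]
        og = build_initial_graph(meta, calls, make_anchors(["a", "b"]))
        assert og.g.number_of_edges() == 0

    def test_same_fpc_good_extent_within_3cm_draws_edge(self):
        meta = make_meta(["a", "b"])
        calls = [OverlapCall("a", "b", "permissive", 6_000, 6_000)]
        anchors = make_anchors(["a", "b"], cms={"a": 10.0, "b": 12.0})
        og = build_initial_graph(meta, calls, anchors)
        assert og.g.has_edge("a", "b")

    def test_cm_gap_above_3_blocks_edge_but_unanchored_party_allows(self):
        meta = make_meta(["a", "b"])
        calls = [OverlapCall("a", "b", "permissive", 6_000, 6_000)]
        anchors = make_anchors(["a", "b"], cms={"a": 10.0, "b": 14.0})
        og = build_initial_graph(meta, calls, anchors)
        assert not og.g.has_edge("a", "b")
        anchors["b"] = BacAnchor("b", UNANCHORED)
        og = build_initial_graph(meta, calls, anchors)
        assert og.g.has_edge("a", "b")

    def test_inconsistent_and_overlong_bacs_are_excluded(self):
        meta = make_meta(["a", "b", "c"])
        meta["c"] = BacMeta("c", 400_000, 30_000, True, False, "fp1", 2.0)
        anchors = make_anchors(["a", "b"])
        anchors["c"] = BacAnchor("c", INCONSISTENT)
        og = build_initial_graph(meta, [], anchors)
        assert og.excluded == {
            "c": "overlong_assembly"
        } or og.excluded.get("c") in {"inconsistent_anchor", "overlong_assembly"}
        assert not og.g.has_node("c")


class TestRollback:
    def _og(self):
        # two path clusters: a-b-c-d-e and f-g-h-i-j
        bacs = list("abcdefghij")
        meta = make_meta(bacs)
        og = OverlapGraph(meta, make_anchors(bacs))
        for b in bacs:
            og.add_node(b)
        for u, v in zip("abcd", "bcde"):
            og.add_edge(u, v, 10_000, "overlap", 1)
        for u, v in zip("fghi", "ghij"):
            og.add_edge(u, v, 10_000, "overlap", 1)
        return og

    def test_branch_creating_candidate_is_rolled_back(self):
        og = self._og()
        before = set(og.g.edges)
        # joining mid-path c to mid-path h leaves e (or a) at rank 2
        committed = add_edges_with_rollback(
            og, [Candidate((("c", "h"),), 1.0, "test")], step=3
        )
        assert committed == []
        assert set(og.g.edges) == before

    def test_end_to_end_candidate_commits_and_merges_clusters(self):
        og = self._og()
        committed = add_edges_with_rollback(
            og, [Candidate((("e", "f"),), 1.0, "test")], step=3
        )
        assert len(committed) == 1
        assert len(og.clusters()) == 1

    def test_commit_order_is_weight_then_lexicographic(self):
        """When two candidates are mutually exclusive, the stronger one
        commits; replaying in the opposite order confirms order matters."""
        og = self._og()
        # two alternative joins of the same cluster ends; committing one
        # makes the other internal (skipped)
        weak = Candidate((("e", "f"),), 1.0, "weak")
        strong = Candidate((("a", "j"),), 2.0, "strong")
        committed = add_edges_with_rollback(og, [weak, strong], step=3)
        assert [c.evidence for c in committed] == ["strong"]
        og2 = self._og()
        committed2 = add_edges_with_rollback(og2, [strong, weak], step=3)
        assert [c.evidence for c in committed2] == ["strong"]

    def test_map_inconsistent_candidate_is_rolled_back(self):
        og = self._og()
        for b in "fghij":
            og.anchors[b] = BacAnchor(b, ANCHORED, MapPosition("chr1", 40.0))
        committed = add_edges_with_rollback(
            og, [Candidate((("e", "f"),), 1.0, "test")], step=3
        )
        assert committed == []
        assert len(og.clusters()) == 2


class TestStats:
    def test_cluster_n50_by_member_mass(self):
        bacs = [f"b{i}" for i in range(11)]
        og = OverlapGraph(make_meta(bacs), make_anchors(bacs))
        for b in bacs:
            og.add_node(b)
        # cluster sizes {4, 3, 2, 1, 1}
        groups = [bacs[0:4], bacs[4:7], bacs[7:9]]
        for grp in groups:
            for u, v in zip(grp[:-1], grp[1:]):
                og.add_edge(u, v, 1_000, "overlap", 1)
        s = og.stats(1)
        assert s["clusters"] == 3
        assert s["bacs_in_clusters"] == 9
        assert s["singletons"] == 2
        assert s["cluster_n50"] == 3


class TestRefinement:
    def _inputs(self, seed=11, **overrides):
        from pseudomap.overlaps import align_assemblies
        from pseudomap.simulate import (
            library_fasta,
            simulate_bac_library,
            simulate_genome,
            simulate_linkage_evidence,
        )

        cfg = clean_config(seed=seed, chr_length=600_000, **overrides)
        genome = simulate_genome(cfg)
        library, truth = simulate_bac_library(genome, cfg)
        ev = simulate_linkage_evidence(genome, library, truth, cfg)
        calls = compute_overlaps(align_assemblies(library_fasta(library)))
        anchors = anchor_all_bacs(ev.wgs_hits, ev.wgs_map, sorted(library))
        anchors = rescue_via_neighbors(
            anchors, calls, {b: a.length for b, a in library.items()}
        )
        return library, truth, ev, calls, anchors

    def test_invariants_hold_after_every_step(self):
        library, truth, ev, calls, anchors = self._inputs()
        meta = meta_from_library(library)
        ref = RefinementEvidence.build(
            calls, om=ev.om, bes=ev.bes, wgs_hits=ev.wgs_hits,
            wgs_map=ev.wgs_map,
        )
        og, stats = run_refinement(meta, calls, anchors, ref)
        og.assert_invariants()  # branch-free + map-consistent at the end
        assert len(stats) == 12
        # cluster count is non-increasing from step 2 on (step 9 may add
        # nodes but merges rather than splits)
        counts = stats["clusters"].tolist()
        assert all(b <= a for a, b in zip(counts[1:-1], counts[2:]))

    def test_steps_1_2_recover_fp_contig_clusters(self):
        """Without redundant clones (which can legitimately bridge
        physical-map gaps) or cross-gap evidence, steps 1-2 recover the
        physical-map runs exactly."""
        library, truth, ev, calls, anchors = self._inputs(
            non_mtp_fraction=0.0
        )
        meta = meta_from_library(library)
        ref = RefinementEvidence.build(calls)
        og, _ = run_refinement(meta, calls, anchors, ref, steps=range(1, 3))
        true_multi = [
            c for c in truth.clusters.values() if len(c["members"]) > 1
        ]
        assert len(og.clusters()) == len(true_multi)
        got = {frozenset(c) for c in og.clusters()}
        expect = {frozenset(c["members"]) for c in true_multi}
        assert got == expect

    def test_full_refinement_merges_only_adjacent_true_clusters(self):
        library, truth, ev, calls, anchors = self._inputs()
        meta = meta_from_library(library)
        ref = RefinementEvidence.build(
            calls, om=ev.om, bes=ev.bes, wgs_hits=ev.wgs_hits,
            wgs_map=ev.wgs_map,
        )
        og, _ = run_refinement(meta, calls, anchors, ref)
        true_of = {
            b: cid
            for cid, c in truth.clusters.items()
            for b in c["members"]
        }
        order_of = {
            cid: (c["chrom"], c["order"]) for cid, c in truth.clusters.items()
        }
        for comp in og.clusters():
            true_ids = {true_of[b] for b in comp if b in true_of}
            chroms = {order_of[t][0] for t in true_ids}
            assert len(chroms) == 1  # never merges across chromosomes
            orders = sorted(order_of[t][1] for t in true_ids)
            assert orders == list(range(orders[0], orders[-1] + 1))

    def test_empty_extra_evidence_makes_steps_3_to_12_noops(self):
        library, truth, ev, calls, anchors = self._inputs()
        meta = meta_from_library(library)
        ref = RefinementEvidence.build(calls)
        og2, _ = run_refinement(meta, calls, anchors, ref, steps=range(1, 3))
        og12, stats = run_refinement(meta, calls, anchors, ref)
        assert set(map(frozenset, og2.clusters())) == set(
            map(frozenset, og12.clusters())
        )
        assert stats.iloc[1]["clusters"] == stats.iloc[-1]["clusters"]


def test_graphml_export_roundtrips_edge_tags(tmp_path):
    import networkx as nx

    bacs = ["a", "b"]
    og = OverlapGraph(make_meta(bacs), make_anchors(bacs))
    for b in bacs:
        og.add_node(b)
    og.add_edge("a", "b", 5_000, "overlap", 1)
    path = tmp_path / "graph.graphml"
    og.write_graphml(path)
    back = nx.read_graphml(path)
    assert back.edges["a", "b"]["evidence"] == "overlap"
    assert back.nodes["a"]["length"] == 100_000


class TestOmSupport:
    def test_confidence_sum_threshold(self):
        import pandas as pd

        bacs = ["a", "b", "c", "d"]
        og = OverlapGraph(make_meta(bacs), make_anchors(bacs))
        for b in bacs:
            og.add_node(b)
        og.add_edge("a", "b", 1_000, "overlap", 1)
        og.add_edge("c", "d", 1_000, "overlap", 1)
        om = pd.DataFrame(
            {
                "bac": ["a", "b", "c", "d"],
                "scaffold": ["a.s1", "b.s1", "c.s1", "d.s1"],
                "om_contig": ["om1"] * 4,
                "om_pos": [0, 50_000, 120_000, 170_000],
                "orientation": [1] * 4,
                "confidence": [13.0, 13.0, 13.0, 13.0],
            }
        )
        from pseudomap.graph import om_join_support

        ok, om_id = om_join_support(
            og, frozenset({"a", "b"}), frozenset({"c", "d"}),
            om_best_alignments(om),
        )
        assert ok and om_id == "om1"  # sums 26 >= 25, gap 70 kb
        om.loc[0, "confidence"] = 5.0  # cluster A sums 18 < 25
        ok, _ = om_join_support(
            og, frozenset({"a", "b"}), frozenset({"c", "d"}),
            om_best_alignments(om),
        )
        assert not ok

    def test_footprint_gap_above_300kb_blocks_join(self):
        import pandas as pd

        from pseudomap.graph import om_join_support

        bacs = ["a", "b", "c", "d"]
        og = OverlapGraph(make_meta(bacs), make_anchors(bacs))
        for b in bacs:
            og.add_node(b)
        og.add_edge("a", "b", 1_000, "overlap", 1)
        og.add_edge("c", "d", 1_000, "overlap", 1)
        om = pd.DataFrame(
            {
                "bac": ["a", "b", "c", "d"],
                "scaffold": ["a.s1", "b.s1", "c.s1", "d.s1"],
                "om_contig": ["om1"] * 4,
                "om_pos": [0, 50_000, 400_001, 450_000],
                "orientation": [1] * 4,
                "confidence": [15.0] * 4,
            }
        )
        ok, _ = om_join_support(
            og, frozenset({"a", "b"}), frozenset({"c", "d"}),
            om_best_alignments(om),
        )
        assert not ok  # 350 kb apart

    def test_reversed_backbone_order_blocks_join(self):
        import pandas as pd

        from pseudomap.graph import om_join_support

        bacs = ["a", "b", "c", "x", "y", "z"]
        og = OverlapGraph(make_meta(bacs), make_anchors(bacs))
        for b in bacs:
            og.add_node(b)
        for u, v in (("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")):
            og.add_edge(u, v, 1_000, "overlap", 1)
        om = pd.DataFrame(
            {
                "bac": ["a", "b", "c", "x", "y", "z"],
                "scaffold": [f"{b}.s1" for b in ["a", "b", "c", "x", "y", "z"]],
                "om_contig": ["om1"] * 6,
                # cluster 1 order agrees; cluster 2 order is reversed
                "om_pos": [0, 10_000, 20_000, 90_000, 80_000, 70_000],
                "orientation": [1] * 6,
                "confidence": [10.0] * 6,
            }
        )
        ok, _ = om_join_support(
            og, frozenset({"a", "b", "c"}), frozenset({"x", "y", "z"}),
            om_best_alignments(om),
        )
        assert not ok
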