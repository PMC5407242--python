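"""Non-redundant sequence construction and gene rescue."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pseudomap.graph import compute_backbone
from pseudomap.nrseq import (
    build_nr,
    rescue_gene_sequences,
    self_redundancy_hits,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def chain_backbone(bacs, weight=10_000):
    g = nx.Graph()
    for u, v in zip(bacs[:-1], bacs[1:]):
        g.add_edge(u, v, weight=weight)
    return compute_backbone(g)


class TestBuildNr:
    def test_identical_scaffolds_collapse_to_one_copy(self, rng):
        seq = random_seq(rng, 5_000)
        bb = chain_backbone(["b1", "b2"])
        nr, prov = build_nr(
            "cl", ["b1", "b2"], {"b1": {"b1.s1": seq}, "b2": {"b2.s1": seq}},
            bb,
        )
        assert len(nr) == 1
        assert next(iter(nr.values())) == seq
        assert len(prov) == 1

    def test_true_overlap_is_subtracted_once(self, rng):
        genome = random_seq(rng, 60_000)
        a, b = genome[:35_000], genome[15_000:]  # 20 kb true overlap
        bb = chain_backbone(["b1", "b2"])
        nr, prov = build_nr(
            "cl", ["b1", "b2"], {"b1": {"b1.s1": a}, "b2": {"b2.s1": b}}, bb
        )
        total = sum(len(s) for s in nr.values())
        expected = len(a) + len(b) - 20_000
        assert abs(total - expected) <= 200  # alignment-edge slack
        assert not self_redundancy_hits(nr, prov, bb)

    def test_no_subtraction_beyond_10_mst_hops(self, rng):
        """Two BACs 11 hops apart sharing a 2 kb duplication keep both
        copies; at 2 hops the duplicate is subtracted."""
        dup = random_seq(rng, 2_000)
        far = [f"b{i:02d}" for i in range(12)]  # b00..b11: 11 hops apart
        scaffolds = {
            b: {f"{b}.s1": random_seq(rng, 3_000)} for b in far
        }
        scaffolds["b00"]["b00.s1"] = dup + random_seq(rng, 1_000)
        scaffolds["b11"]["b11.s1"] = random_seq(rng, 1_000) + dup
        nr, _ = build_nr("cl", far, scaffolds, chain_backbone(far))
        copies = sum(dup in s for s in nr.values())
        assert copies == 2
        near = ["b00", "b01", "b02"]
        nr2, _ = build_nr(
            "cl2", near, {b: scaffolds[b] for b in near},
            chain_backbone(near),
        )
        # b02 is 2 hops from b00: only one copy survives
        scaffolds2 = {
            "b00": scaffolds["b00"],
            "b01": scaffolds["b01"],
            "b02": {"b02.s1": random_seq(rng, 1_000) + dup},
        }
        nr3, _ = build_nr("cl3", near, scaffolds2, chain_backbone(near))
        assert sum(dup in s for s in nr3.values()) == 1

    def test_terminal_n_runs_are_trimmed(self, rng):
        seq = "N" * 30 + random_seq(rng, 1_000) + "N" * 20
        nr, prov = build_nr("cl", ["b1"], {"b1": {"b1.s1": seq}}, None)
        (frag,) = nr.values()
        assert not frag.startswith("N") and not frag.endswith("N")
        assert len(frag) == 1_000
        r = prov.iloc[0]
        assert (r.scf_start, r.scf_end) == (30, 1_030)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError, match="empty cluster"):
            build_nr("cl", [], {}, None)

    def test_remnants_under_500_proper_nt_are_discarded(self, rng):
        big = random_seq(rng, 5_000)
        small = big[:700] + big[4_600:]  # both pieces < 500 after subtraction
        bb = chain_backbone(["b1", "b2"])
        nr, _ = build_nr(
            "cl", ["b1", "b2"],
            {"b1": {"b1.s1": big}, "b2": {"b2.s1": small}}, bb,
        )
        # 'small' aligns over its full length in two <500 pieces... the
        # 700 bp prefix is subtracted entirely; nothing under 500 survives
        assert all(len(s) >= 500 for s in nr.values())


class TestRescue:
    def _tables(self, nr_frac, all_frac):
        nr_hits = pd.DataFrame(
            [("g1", "cl_f0001", nr_frac)],
            columns=["gene", "target", "cds_fraction"],
        )
        all_hits = pd.DataFrame(
            [("g1", "b2.s1", all_frac)],
            columns=["gene", "target", "cds_fraction"],
        )
        return nr_hits, all_hits

    def test_swap_triggered_at_5_point_gain(self, rng):
        base = random_seq(rng, 4_000)
        better = base[1_000:3_000] + random_seq(rng, 1_000)
        nr = {"cl_f0001": base}
        prov = pd.DataFrame(
            [("cl_f0001", 0, 4_000, "b1", "b1.s1", 0, 4_000, 1)],
            columns=["seq", "start", "end", "bac", "scaffold", "scf_start",
                     "scf_end", "strand"],
        )
        nr_hits, all_hits = self._tables(0.60, 0.66)
        out, prov2, chrun = rescue_gene_sequences(
            nr_hits, all_hits, pd.DataFrame(columns=["gene", "target",
                                                     "cds_fraction"]),
            nr, prov, {"b2": "cl"}, {"b2.s1": better}, {},
        )
        assert "cl_swap_b2.s1" in out
        # the covered middle of the old record was removed
        assert "cl_f0001" not in out
        assert any(n.startswith("cl_f0001:") for n in out)

    def test_no_swap_below_5_point_gain(self, rng):
        base = random_seq(rng, 4_000)
        nr = {"cl_f0001": base}
        prov = pd.DataFrame(
            [("cl_f0001", 0, 4_000, "b1", "b1.s1", 0, 4_000, 1)],
            columns=["seq", "start", "end", "bac", "scaffold", "scf_start",
                     "scf_end", "strand"],
        )
        nr_hits, all_hits = self._tables(0.60, 0.64)
        out, _, _ = rescue_gene_sequences(
            nr_hits, all_hits, pd.DataFrame(columns=["gene", "target",
                                                     "cds_fraction"]),
            nr, prov, {"b2": "cl"}, {"b2.s1": random_seq(rng, 3_000)}, {},
        )
        assert out == nr

    def test_wgs_only_gene_contributes_chrun_remnant(self, rng):
        nr = {"cl_f0001": random_seq(rng, 4_000)}
        prov = pd.DataFrame(
            [("cl_f0001", 0, 4_000, "b1", "b1.s1", 0, 4_000, 1)],
            columns=["seq", "start", "end", "bac", "scaffold", "scf_start",
                     "scf_end", "strand"],
        )
        wgs_hits = pd.DataFrame(
            [("g9", "wgs_1", 0.9)], columns=["gene", "target", "cds_fraction"]
        )
        carrier = random_seq(rng, 2_500)
        _, _, chrun = rescue_gene_sequences(
            pd.DataFrame(columns=["gene", "target", "cds_fraction"]),
            pd.DataFrame(columns=["gene", "target", "cds_fraction"]),
            wgs_hits, nr, prov, {}, {}, {"wgs_1": carrier},
        )
        assert len(chrun) == 1
        assert next(iter(chrun.values())) == carrier

    def test_coverage_fraction_out_of_range_raises(self):
        bad = pd.DataFrame(
            [("g", "t", 1.2)], columns=["gene", "target", "cds_fraction"]
        )
        with pytest.raises(ValueError, match="cds_fraction"):
            rescue_gene_sequences(
                bad, bad, bad, {}, pd.DataFrame(
                    columns=["seq", "start", "end", "bac", "scaffold",
                             "scf_start", "scf_end", "strand"]
                ), {}, {}, {},
            )


def test_cluster_nr_matches_true_span_on_clean_run(clean_run):
    """Per multi-member cluster, NR length is within 1% of the true genomic
    span, and the NR has no residual redundancy within 10 MST hops."""
    from pseudomap.intervals import merge_intervals

    res = clean_run
    checked = 0
    for cid, members in res.clusters.items():
        if len(members) < 2:
            continue
        ivs = [
            (a, b)
            for m in members
            for c, a, b in res.truth.bacs[m].genome_intervals()
        ]
        span = sum(b - a for a, b in merge_intervals(ivs, max_gap=2_000))
        prov = res.provenance[res.provenance["seq"].str.startswith(cid + "_")]
        nr_len = int((prov["end"] - prov["start"]).sum())
        assert abs(nr_len - span) / span < 0.01, cid
        bb = res.graph.backbone(frozenset(members))
        frags = {s: res.nr[s] for s in prov["seq"]}
        assert not self_redundancy_hits(frags, prov, bb)
        checked += 1
    assert checked >= 2
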