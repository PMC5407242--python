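"""Genotype filtering, consensus maps and majority-rule anchoring."""

import numpy as np
import pandas as pd
import pytest

from pseudomap.anchor import (
    ANCHORED,
    INCONSISTENT,
    UNANCHORED,
    BacAnchor,
    MapPosition,
    anchor_all_bacs,
    anchor_bac,
    anchor_cluster,
    filter_genotype_matrix,
    merge_consensus_map,
    rescue_via_neighbors,
)
from pseudomap.overlaps import OverlapCall


def matrix(calls, depth, qual, site_qual):
    idx = [f"v{i}" for i in range(len(calls))]
    cols = [f"s{i}" for i in range(len(calls[0]))]
    return (
        pd.DataFrame(calls, index=idx, columns=cols, dtype=np.int8),
        pd.DataFrame(depth, index=idx, columns=cols),
        pd.DataFrame(qual, index=idx, columns=cols),
        pd.Series(site_qual, index=idx),
    )


class TestGenotypeFilter:
    def test_popseq_hom_call_with_zero_depth_goes_missing(self):
        c, d, q, sq = matrix(
            [[0, 2, 0, 2]], [[0, 10, 10, 10]], [[40] * 4], [100]
        )
        out = filter_genotype_matrix(c, d, q, sq, "popseq")
        assert out.iloc[0, 0] == -1
        assert out.iloc[0, 1] == 2

    def test_popseq_het_needs_depth_3_and_quality_5(self):
        c, d, q, sq = matrix(
            [[1, 1, 0, 2]], [[2, 3, 5, 5]], [[40, 4, 40, 40]], [100]
        )
        out = filter_genotype_matrix(c, d, q, sq, "popseq")
        assert out.iloc[0, 0] == -1  # depth 2 < 3
        assert out.iloc[0, 1] == -1  # quality 4 < 5

    def test_gbs_maf_below_30pct_is_dropped(self):
        # 3/12 minor alleles -> MAF 0.25 < 0.30
        calls = [[0] * 9 + [2] * 3, [0] * 6 + [2] * 6]
        d = [[10] * 12] * 2
        q = [[40] * 12] * 2
        c, dd, qq, sq = matrix(calls, d, q, [100, 100])
        out = filter_genotype_matrix(c, dd, qq, sq, "gbs", min_sample_calls=1)
        assert list(out.index) == ["v1"]

    def test_gbs_hets_are_ignored(self):
        c, d, q, sq = matrix(
            [[1] + [0, 2] * 6, [0, 2] * 6 + [0]],
            [[10] * 13] * 2,
            [[40] * 13] * 2,
            [100, 100],
        )
        out = filter_genotype_matrix(c, d, q, sq, "gbs", min_sample_calls=1)
        assert out.loc["v0", "s0"] == -1
        assert (out.loc["v0"].iloc[1:] != -1).all()

    def test_all_passing_matrix_is_unchanged(self):
        calls = [[0, 2, 0, 2], [2, 0, 2, 0]]
        c, d, q, sq = matrix(calls, [[10] * 4] * 2, [[40] * 4] * 2, [100, 100])
        out = filter_genotype_matrix(c, d, q, sq, "popseq")
        assert out.values.tolist() == calls

    def test_unknown_profile_raises(self):
        c, d, q, sq = matrix([[0]], [[1]], [[40]], [100])
        with pytest.raises(ValueError, match="profile"):
            filter_genotype_matrix(c, d, q, sq, "other")


class TestConsensusMap:
    def _map(self, contigs, cms, chrom="1H"):
        return pd.DataFrame(
            {"contig": contigs, "chrom": chrom, "cm": cms}
        )

    def test_identical_maps_yield_primary(self):
        contigs = [f"c{i}" for i in range(20)]
        cms = np.linspace(0, 100, 20)
        out = merge_consensus_map(self._map(contigs, cms),
                                  self._map(contigs, cms))
        anchored = out[out["status"] == ANCHORED]
        assert len(anchored) == 20
        assert np.allclose(np.sort(anchored["cm"]), np.sort(cms))

    def test_secondary_only_contig_interpolated_on_linear_relation(self):
        """Exact linear maps cm2 = 2*cm1: a secondary-only contig at
        cm2 = 10 lands at consensus cm 5 +/- 0.5."""
        contigs = [f"c{i}" for i in range(30)]
        cm1 = np.linspace(0, 50, 30)
        prim = self._map(contigs, cm1)
        sec = self._map(contigs + ["extra"], list(2 * cm1) + [10.0])
        out = merge_consensus_map(prim, sec).set_index("contig")
        assert out.loc["extra", "status"] == ANCHORED
        assert out.loc["extra", "cm"] == pytest.approx(5.0, abs=0.5)

    def test_disagreement_above_5_cm_is_unanchored(self):
        contigs = [f"c{i}" for i in range(20)]
        cm1 = np.linspace(0, 100, 20)
        cm2 = cm1.copy()
        cm2[10] += 6.0  # disagrees by 6 cM
        out = merge_consensus_map(
            self._map(contigs, cm1), self._map(contigs, cm2)
        ).set_index("contig")
        assert out.loc["c10", "status"] == UNANCHORED

    def test_too_few_shared_contigs_leaves_secondary_unanchored(self):
        prim = self._map(["a", "b"], [0.0, 1.0])
        sec = self._map(["a", "b", "x"], [0.0, 1.0, 0.5])
        out = merge_consensus_map(prim, sec).set_index("contig")
        assert out.loc["x", "status"] == UNANCHORED


class TestAnchorBac:
    def hits(self, chroms, cms):
        return pd.DataFrame(
            {
                "wgs_contig": [f"w{i}" for i in range(len(chroms))],
                "chrom": chroms,
                "cm": cms,
            }
        )

    def test_consistent_hits_anchor_at_median(self):
        a = anchor_bac("b", self.hits(["3H"] * 10, np.linspace(10, 13, 10)))
        assert a.status == ANCHORED
        assert a.chrom == "3H"
        assert a.cm == pytest.approx(11.5)

    def test_80pct_majority_is_inconsistent(self):
        a = anchor_bac("b", self.hits(["3H"] * 8 + ["5H"] * 2, [10] * 10))
        assert a.status == INCONSISTENT

    def test_sd_above_3_cm_is_inconsistent(self):
        cms = [0.0, 10.0] * 5  # sd ~ 5.3
        a = anchor_bac("b", self.hits(["3H"] * 10, cms))
        assert a.status == INCONSISTENT

    def test_no_hits_is_unanchored(self):
        a = anchor_bac("b", self.hits([], []))
        assert a.status == UNANCHORED

    def test_duplicate_contig_hits_count_once(self):
        h = self.hits(["3H"] * 9 + ["5H"], [10] * 10)
        h.loc[9, "wgs_contig"] = "w0"  # duplicate of a 3H contig
        assert anchor_bac("b", h).status == ANCHORED

    def test_anchoring_is_idempotent(self):
        h = self.hits(["1H"] * 5, [1, 2, 3, 4, 5])
        a1 = anchor_bac("b", h)
        a2 = anchor_bac("b", h)
        assert a1 == a2


class TestRescue:
    def _anchors(self):
        return {
            "u": BacAnchor("u", UNANCHORED),
            "n1": BacAnchor("n1", ANCHORED, MapPosition("1H", 10.0)),
            "n2": BacAnchor("n2", ANCHORED, MapPosition("1H", 12.0)),
        }

    def _calls(self):
        return [
            OverlapCall("n1", "u", "stringent", 20_000, 20_000),
            OverlapCall("n2", "u", "stringent", 20_000, 20_000),
        ]

    def test_rescued_at_arithmetic_mean(self):
        lengths = {"u": 100_000, "n1": 100_000, "n2": 100_000}
        out = rescue_via_neighbors(self._anchors(), self._calls(), lengths)
        assert out["u"].status == ANCHORED
        assert out["u"].cm == pytest.approx(11.0)

    def test_bac_over_300kb_is_never_rescued(self):
        lengths = {"u": 310_000, "n1": 100_000, "n2": 100_000}
        out = rescue_via_neighbors(self._anchors(), self._calls(), lengths)
        assert out["u"].status == UNANCHORED

    def test_neighbours_on_two_chromosomes_block_rescue(self):
        anchors = self._anchors()
        anchors["n2"] = BacAnchor("n2", ANCHORED, MapPosition("2H", 12.0))
        lengths = {"u": 100_000, "n1": 100_000, "n2": 100_000}
        out = rescue_via_neighbors(anchors, self._calls(), lengths)
        assert out["u"].status == UNANCHORED

    def test_rescue_never_alters_anchored_bacs(self):
        anchors = self._anchors()
        lengths = {"u": 100_000, "n1": 100_000, "n2": 100_000}
        out = rescue_via_neighbors(anchors, self._calls(), lengths)
        assert out["n1"] == anchors["n1"]
        assert out["n2"] == anchors["n2"]


class TestAnchorCluster:
    def members(self, cms, chrom="1H"):
        return [
            BacAnchor(f"b{i}", ANCHORED, MapPosition(chrom, cm))
            for i, cm in enumerate(cms)
        ]

    def test_agreeing_members_anchor_cluster(self):
        a = anchor_cluster(self.members([20, 21, 22]))
        assert a.status == ANCHORED
        assert a.position.cm == 21

    def test_sd_above_5_cm_is_inconsistent(self):
        a = anchor_cluster(self.members([0, 11.1]))  # sd ~ 7.8
        assert a.status == INCONSISTENT

    def test_no_anchored_members_is_unanchored(self):
        a = anchor_cluster([BacAnchor("b", UNANCHORED)])
        assert a.status == UNANCHORED


def test_parameter_recovery_on_synthetic_library(small_dataset):
    """With 0.5 cM map noise, nearly all non-chimeric BACs anchor to their
    true chromosome."""
    _, _, library, truth, ev = small_dataset
    anchors = anchor_all_bacs(ev.wgs_hits, ev.wgs_map, sorted(library))
    ok = 0
    total = 0
    for b, anc in anchors.items():
        if truth.bacs[b].chimeric:
            continue
        total += 1
        if anc.status == ANCHORED and anc.chrom == truth.bacs[b].primary_span()[0]:
            ok += 1
    assert ok / total >= 0.95
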