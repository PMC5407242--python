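"""Pseudomolecule assembly, splitting, masking and summary tables."""

import numpy as np
import pandas as pd
import pytest

from pseudomap import load_reference_table
from pseudomap.align import Hsp, revcomp
from pseudomap.pseudo import (
    build_pseudomolecules,
    mask_residual_redundancy,
    pct,
    reconstruct_from_placement,
    split_pseudomolecules,
    summarize_anchoring,
    summarize_genetic_map,
    summarize_wgs_anchoring,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def simple_build(rng, orientation="+"):
    nr = {"cl1_f0001": random_seq(rng, 1_000), "cl1_f0002": random_seq(rng, 1_000)}
    layout = pd.DataFrame(
        [("cl1", "cl1_f0001", 0, 1_000), ("cl1", "cl1_f0002", 1_100, 1_000)],
        columns=["cluster", "seq", "offset", "length"],
    )
    order = pd.DataFrame(
        [("chr1", 0, "cl1", 5.0)], columns=["chrom", "rank", "cluster", "cm"]
    )
    return build_pseudomolecules(order, {"cl1": orientation}, nr, layout), nr


class TestBuild:
    def test_two_1kb_fragments_give_2100_bp_record(self, rng):
        pset, _ = simple_build(rng)
        assert len(pset.fasta["chr1"]) == 2_100
        assert pset.fasta["chr1"][1_000:1_100] == "N" * 100

    def test_flipped_cluster_reverses_order_and_complements(self, rng):
        pset_f, nr = simple_build(rng, orientation="-")
        chrom = pset_f.fasta["chr1"]
        assert chrom[:1_000] == revcomp(nr["cl1_f0002"])
        assert chrom[1_100:] == revcomp(nr["cl1_f0001"])
        strands = set(pset_f.placement["strand"])
        assert strands == {"-"}

    def test_placement_roundtrip_is_byte_identical(self, rng):
        pset, nr = simple_build(rng, orientation="-")
        rebuilt = reconstruct_from_placement(pset.placement, nr)
        assert rebuilt == pset.fasta

    def test_missing_fragment_is_reported_by_name(self, rng):
        nr = {"cl1_f0001": random_seq(rng, 1_000)}
        layout = pd.DataFrame(
            [("cl1", "cl1_f0001", 0, 1_000), ("cl1", "ghost", 1_100, 500)],
            columns=["cluster", "seq", "offset", "length"],
        )
        order = pd.DataFrame(
            [("chr1", 0, "cl1", 5.0)],
            columns=["chrom", "rank", "cluster", "cm"],
        )
        with pytest.raises(KeyError, match="ghost"):
            build_pseudomolecules(order, {}, nr, layout)

    def test_unplaced_clusters_go_to_chrun(self, rng):
        nr = {"cl1_f0001": random_seq(rng, 1_000), "un_f0001": random_seq(rng, 800)}
        layout = pd.DataFrame(
            [("cl1", "cl1_f0001", 0, 1_000), ("un", "un_f0001", 0, 800)],
            columns=["cluster", "seq", "offset", "length"],
        )
        order = pd.DataFrame(
            [("chr1", 0, "cl1", 5.0)],
            columns=["chrom", "rank", "cluster", "cm"],
        )
        pset = build_pseudomolecules(order, {}, nr, layout,
                                     unplaced_clusters=["un"])
        assert "chrUn" in pset.fasta
        assert len(pset.fasta["chrUn"]) == 800


def test_agp_rows_cover_record_contiguously(rng):
    from pseudomap.pseudo import placement_to_agp

    pset, _ = simple_build(rng)
    agp = placement_to_agp(pset.placement)
    assert list(agp["component_type"]) == ["W", "U", "W"]
    # 1-based inclusive coordinates tile the record without holes
    assert agp.iloc[0]["object_beg"] == 1
    for prev, nxt in zip(agp.itertuples(), list(agp.itertuples())[1:]):
        assert nxt.object_beg == prev.object_end + 1
    assert agp.iloc[-1]["object_end"] == 2_100


class TestSplit:
    def _pset(self, rng, n_frags=6, frag=20_000):
        nr = {f"c_f{i:04d}": random_seq(rng, frag) for i in range(n_frags)}
        layout = pd.DataFrame(
            [("c", name, i * (frag + 100), frag)
             for i, name in enumerate(sorted(nr))],
            columns=["cluster", "seq", "offset", "length"],
        )
        order = pd.DataFrame(
            [("chr1", 0, "c", 1.0)], columns=["chrom", "rank", "cluster", "cm"]
        )
        return build_pseudomolecules(order, {"c": "+"}, nr, layout), nr

    def test_oversize_record_splits_below_limit(self, rng):
        pset, _ = self._pset(rng)
        split, conv = split_pseudomolecules(pset.fasta, pset.placement,
                                            limit=70_000)
        assert all(len(s) <= 70_000 for s in split.values())
        assert len(split) >= 2

    def test_small_record_is_unchanged(self, rng):
        pset, _ = self._pset(rng, n_frags=2)
        split, conv = split_pseudomolecules(pset.fasta, pset.placement,
                                            limit=10**9)
        assert split == pset.fasta

    def test_conversion_bed_roundtrips_coordinates(self, rng):
        pset, _ = self._pset(rng)
        split, conv = split_pseudomolecules(pset.fasta, pset.placement,
                                            limit=70_000)
        full = pset.fasta["chr1"]
        for r in conv.itertuples():
            assert split[r.part][r.part_start:r.part_end] == \
                full[r.start:r.end]

    def test_single_fragment_above_limit_raises(self, rng):
        pset, _ = self._pset(rng, n_frags=1)
        with pytest.raises(ValueError, match="single fragment"):
            split_pseudomolecules(pset.fasta, pset.placement, limit=10_000)


class TestMask:
    def hsp(self, q, s, qiv, siv, length=6_000, identity=99.9):
        return Hsp(q, s, identity, length, 0, qiv[0] + 1, qiv[1], siv[0] + 1,
                   siv[1])

    def test_chrun_copy_is_masked_against_chromosome(self, rng):
        fasta = {"3H": random_seq(rng, 20_000), "chrUn": random_seq(rng, 20_000)}
        h = self.hsp("chrUn", "3H", (1_000, 7_000), (2_000, 8_000))
        masked, bed = mask_residual_redundancy(fasta, [h])
        assert masked["chrUn"][1_000:7_000] == "N" * 6_000
        assert "N" * 100 not in masked["3H"]
        assert set(bed["class"]) == {"chrun_redundant"}

    def test_sub_5kb_hit_is_not_a_pr_region(self, rng):
        fasta = {"3H": random_seq(rng, 20_000), "chrUn": random_seq(rng, 20_000)}
        h = self.hsp("chrUn", "3H", (1_000, 5_900), (2_000, 6_900),
                     length=4_900)
        masked, bed = mask_residual_redundancy(fasta, [h])
        assert bed.empty
        assert masked == fasta

    def test_inter_chromosomal_chimera_region_is_masked(self, rng):
        fasta = {"1H": random_seq(rng, 20_000), "2H": random_seq(rng, 20_000)}
        h = self.hsp("1H", "2H", (0, 6_000), (0, 6_000))
        masked, bed = mask_residual_redundancy(fasta, [h])
        # both regions hit only another chromosome -> both class (i)
        assert masked["1H"][:6_000] == "N" * 6_000
        assert masked["2H"][:6_000] == "N" * 6_000
        assert set(bed["class"]) == {"inter_chromosomal_chimera"}

    def test_masking_conserves_record_lengths(self, rng):
        fasta = {"1H": random_seq(rng, 20_000), "chrUn": random_seq(rng, 9_000)}
        h = self.hsp("chrUn", "1H", (500, 6_500), (2_000, 8_000))
        masked, _ = mask_residual_redundancy(fasta, [h])
        assert {k: len(v) for k, v in masked.items()} == \
            {k: len(v) for k, v in fasta.items()}

    def test_same_chromosome_pair_masks_arbitrary_larger_key(self, rng):
        fasta = {"1H": random_seq(rng, 40_000)}
        h = self.hsp("1H", "1H", (0, 6_000), (20_000, 26_000))
        masked, bed = mask_residual_redundancy(fasta, [h])
        assert masked["1H"][20_000:26_000] == "N" * 6_000
        assert masked["1H"][:6_000] == fasta["1H"][:6_000]
        assert set(bed["class"]) == {"arbitrary_copy"}


class TestSummaries:
    def test_anchoring_totals_match_published_barley_numbers(self):
        table = load_reference_table("barley_bac_anchoring")
        out = summarize_anchoring(table).set_index("chrom")
        assert out.loc["total", "sequenced"] == 87_075
        assert out.loc["total", "anchored"] == 78_693
        assert out.loc["total", "anchored_pct"] == 90.4

    def test_gbs_map_totals(self):
        table = load_reference_table("barley_gbs_map")
        out = summarize_genetic_map(table).set_index("chrom")
        assert out.loc["total", "snps"] == 2_637
        assert out.loc["total", "bins"] == 1_498
        assert out.loc["total", "map_cm"] == 996.8

    def test_wgs_map_totals(self):
        table = load_reference_table("barley_popseq_wgs_map")
        out = summarize_wgs_anchoring(table).set_index("chrom")
        assert out.loc["total", "contigs"] == 791_176
        assert out.loc["total", "length_mb"] == 1_220.9

    def test_percentage_rounding_convention(self):
        assert pct(78_693, 87_075) == 90.4
        assert pct(1, 3) == 33.3
        assert np.isnan(pct(1, 0))

    def test_empty_input_no_crash(self):
        empty = pd.DataFrame(columns=["chrom", "sequenced", "anchored"])
        out = summarize_anchoring(empty)
        assert out.loc[0, "chrom"] == "total"
        assert out.loc[0, "sequenced"] == 0
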