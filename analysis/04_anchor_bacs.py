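#!/usr/bin/env python
"""Genetic anchoring: genotype-matrix filtering, consensus map, BAC anchors.

Demonstrates the two genotype-filtering profiles on simulated RIL
matrices, merges a primary/secondary map pair into a consensus, anchors
every BAC by majority rule and rescues unanchored clones through their
overlap neighbours. Writes the anchor table and an anchoring summary.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import bench_config, outdir

from pseudomap import anchor, overlaps, simulate
from pseudomap.pseudo import summarize_anchoring


def main() -> None:
    cfg = bench_config()
    out = outdir("anchoring")
    genome = simulate.simulate_genome(cfg)
    library, truth = simulate.simulate_bac_library(genome, cfg)
    ev = simulate.simulate_linkage_evidence(genome, library, truth, cfg)

    # genotype-matrix filtering on the simulated RIL data
    for profile in ("popseq", "gbs"):
        gm = ev.genotypes[profile]
        filtered = anchor.filter_genotype_matrix(
            gm["calls"], gm["depth"], gm["qual"], gm["site_qual"], profile,
            min_sample_calls=50,  # scaled to the benchmark marker count
        )
        print(f"{profile} filter: {gm['calls'].shape} -> {filtered.shape}")
    print("(the gbs profile is deliberately severe: its 10% missing-data "
          "ceiling retains only the best-genotyped markers)")

    # consensus of the map with a coarser secondary version of itself
    secondary = ev.wgs_map.rename(columns={"wgs_contig": "contig"}).copy()
    secondary["cm"] = secondary["cm"] * 1.05 + 0.3  # different scale
    primary = ev.wgs_map.rename(columns={"wgs_contig": "contig"})
    consensus = anchor.merge_consensus_map(primary, secondary.iloc[::2])
    n_un = (consensus["status"] != anchor.ANCHORED).sum()
    print(f"consensus map: {len(consensus)} contigs, {n_un} left unanchored")

    # majority-rule anchoring + neighbour rescue
    calls = overlaps.compute_overlaps(
        overlaps.align_assemblies(simulate.library_fasta(library))
    )
    anchors = anchor.anchor_all_bacs(ev.wgs_hits, ev.wgs_map, sorted(library))
    n_before = sum(a.status == anchor.ANCHORED for a in anchors.values())
    anchors = anchor.rescue_via_neighbors(
        anchors, calls, {b: a.length for b, a in library.items()}
    )
    rows = [
        (b, a.status, a.chrom or "", a.cm if a.cm is not None else "")
        for b, a in sorted(anchors.items())
    ]
    pd.DataFrame(rows, columns=["bac", "status", "chrom", "cm"]).to_csv(
        out / "bac_anchors.tsv", sep="\t", index=False
    )
    n_after = sum(a.status == anchor.ANCHORED for a in anchors.values())
    per_chrom = []
    for chrom in sorted(truth.chromosomes):
        seq = [b for b in library
               if truth.bacs[b].primary_span()[0] == chrom]
        anch = [b for b in seq if anchors[b].status == anchor.ANCHORED]
        per_chrom.append((chrom, len(seq), len(anch)))
    summary = summarize_anchoring(
        pd.DataFrame(per_chrom, columns=["chrom", "sequenced", "anchored"])
    )
    summary.to_csv(out / "anchoring_summary.tsv", sep="\t", index=False)
    print(f"anchored {n_before} BACs directly, {n_after - n_before} more by "
          f"neighbour rescue ({100 * n_after / len(library):.1f}% total)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
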