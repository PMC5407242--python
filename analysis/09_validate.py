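#!/usr/bin/env python
"""Validate the reconstruction against the simulator's truth set.

Reports base-placement multiplicity, cluster-order recovery, marker
collinearity, and the summary-table arithmetic on the bundled published
per-chromosome statistics.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import bench_config, outdir

from pseudomap import evaluate, load_reference_table
from pseudomap.pipeline import run_pipeline
from pseudomap.pseudo import summarize_anchoring, summarize_genetic_map


def main() -> None:
    cfg = bench_config()
    out = outdir("validation")
    res = run_pipeline(cfg)

    stats = evaluate.genome_placement_stats(res)
    print(f"genome bases placed exactly once: "
          f"{100 * stats['fraction_once']:.2f}% "
          f"(multiply placed: {100 * stats['fraction_multi']:.3f}%)")

    rec = evaluate.order_recovery(res)
    rec.to_csv(out / "order_recovery.tsv", sep="\t", index=False)
    print(rec.to_string(index=False))

    coll = evaluate.marker_collinearity(res)
    coll.to_csv(out / "collinearity.tsv", sep="\t", index=False)
    print("marker collinearity (Spearman rho, pseudomolecule vs cM):")
    print(coll.to_string(index=False))

    print("\npublished-table arithmetic checks:")
    anch = summarize_anchoring(
        load_reference_table("barley_bac_anchoring")
    ).set_index("chrom")
    print(f"  anchored BACs total: {int(anch.loc['total', 'anchored']):,} "
          f"of {int(anch.loc['total', 'sequenced']):,} "
          f"({anch.loc['total', 'anchored_pct']}%)")
    gbs = summarize_genetic_map(
        load_reference_table("barley_gbs_map")
    ).set_index("chrom")
    print(f"  GBS map: {int(gbs.loc['total', 'snps']):,} SNPs in "
          f"{int(gbs.loc['total', 'bins']):,} bins, "
          f"{gbs.loc['total', 'map_cm']} cM")


if __name__ == "__main__":
    main()
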