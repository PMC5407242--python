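#!/usr/bin/env python
"""Emit pseudomolecules, mask residual redundancy and split large records.

Writes the pseudomolecule FASTA, the placement BED, the residual-redundancy
mask BED and a split version (demonstrated with a reduced size limit so the
benchmark records actually split).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import bench_config, outdir

from pseudomap import simulate
from pseudomap.align import align_pairwise
from pseudomap.pipeline import run_pipeline
from pseudomap.pseudo import (
    mask_residual_redundancy,
    placement_to_agp,
    split_pseudomolecules,
)


def main() -> None:
    cfg = bench_config()
    out = outdir("pseudomolecules")
    res = run_pipeline(cfg)
    pset = res.pseudomolecules
    simulate.write_fasta(pset.fasta, out / "pseudomolecules.fasta")
    pset.placement.to_csv(out / "placement.bed", sep="\t", index=False)
    placement_to_agp(pset.placement).to_csv(
        out / "placement.agp", sep="\t", index=False, header=False
    )

    # residual redundancy: self-align the pseudomolecules
    self_hits = align_pairwise(
        pset.fasta, pset.fasta, min_identity=99.8, min_length=5_000,
        skip_self=True,
    )
    masked, mask_bed = mask_residual_redundancy(pset.fasta, self_hits)
    mask_bed.to_csv(out / "mask.bed", sep="\t", index=False)
    simulate.write_fasta(masked, out / "pseudomolecules_masked.fasta")

    # split demonstration at a reduced limit (the real limit is 512 Mb)
    split, conv = split_pseudomolecules(masked, pset.placement, limit=600_000)
    simulate.write_fasta(split, out / "pseudomolecules_split.fasta")
    conv.to_csv(out / "split_conversion.bed", sep="\t", index=False)

    for chrom, seq in pset.fasta.items():
        print(f"{chrom}: {len(seq):,} bp, "
              f"{(pset.placement['chrom'] == chrom).sum()} fragments")
    print(f"masked {int((mask_bed['end'] - mask_bed['start']).sum()):,} bp "
          f"in {len(mask_bed)} residual-redundancy regions")
    print(f"split into {len(split)} records at a 600 kb limit")


if __name__ == "__main__":
    main()
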