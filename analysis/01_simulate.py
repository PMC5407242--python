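#!/usr/bin/env python
"""Generate the synthetic benchmark: genome, BAC library, evidence, truth.

Writes the genome and BAC scaffold FASTA, the evidence tables (physical
map, genetic map, WGS hits, optical map, BAC ends) and the truth set under
results/simulation/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import bench_config, outdir

from pseudomap import simulate


def main() -> None:
    cfg = bench_config()
    out = outdir("simulation")
    genome = simulate.simulate_genome(cfg)
    library, truth = simulate.simulate_bac_library(genome, cfg)
    evidence = simulate.simulate_linkage_evidence(genome, library, truth, cfg)

    simulate.write_fasta(genome.chromosomes, out / "genome.fasta")
    simulate.write_fasta(simulate.library_fasta(library), out / "bacs.fasta")
    evidence.fpc.to_csv(out / "fp_contigs.tsv", sep="\t", index=False)
    evidence.wgs_map.to_csv(out / "wgs_map.tsv", sep="\t", index=False)
    evidence.wgs_hits.to_csv(out / "wgs_hits.tsv", sep="\t", index=False)
    evidence.om.to_csv(out / "om_alignments.tsv", sep="\t", index=False)
    evidence.bes.to_csv(out / "bes_hits.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")

    n_mtp = sum(t.is_mtp for t in truth.bacs.values())
    print(f"genome: {cfg.n_chromosomes} x {cfg.chr_length / 1e6:.1f} Mb")
    print(f"BACs: {len(library)} ({n_mtp} MTP), "
          f"{len(truth.fp_contigs)} FP contigs, "
          f"{len(evidence.wgs_map)} WGS map contigs")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
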