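# Methods

This note documents the models, parameters and numerical choices behind
`pseudomap`: what the integration pipeline assumes, what the synthetic
benchmark does and does not emulate, and where the design was genuinely
open.

## The integration model

The pipeline assumes a *linear* genome assembled hierarchically: clone
inserts (~50–150 kb) tile each chromosome with substantial overlaps along
a minimum tiling path, plus redundant non-MTP clones. Under that
assumption, the pairwise-overlap graph of correct assemblies must be
locally path-like: every BAC is either on the linear backbone of its
cluster or attached to exactly one backbone clone (rank ≤ 1; rank-1 nodes
are expected because redundant clones were sequenced). Any node at rank
> 1 — a *branch* — indicates a spurious alignment or a chimeric assembly,
and every refinement step is therefore followed by branch removal or
rollback. The second structural invariant is map consistency: all anchored
members of a cluster must lie on one chromosome with a cM standard
deviation ≤ 5. Chimeric clones violate one of the two invariants almost
surely: a two-chromosome chimera fails the 90% majority rule, a
two-locus single-chromosome chimera fails the 3 cM spread rule, and both
are excluded from the graph at step 1 (step 9 may deliberately re-admit a
flagged single-chromosome chimera when it creates no branch; its redundant
half is caught later by residual-redundancy masking).

### Thresholds

All sequence-level thresholds are the established ones for this kind of
data (same-genotype assemblies, so near-identity is expected):

| quantity | value | role |
| --- | --- | --- |
| stringent overlap | HSP ≥ 5 kb, ≥ 99.8% id | cross-FPC cluster joins |
| permissive overlap | HSP ≥ 2 kb, ≥ 99.5% id | within-FPC edges |
| extent HSPs | ≥ 500 bp, ≥ 99.5% id, gaps < 200 bp merged | edge weights |
| anchoring hits | ≥ 1 kb, ≥ 99.8% id, distinct contigs | majority rule |
| BAC anchor | ≥ 90% modal chromosome, sd ≤ 3 cM, median cM | |
| cluster anchor | one chromosome, sd ≤ 5 cM, median cM | |
| neighbour rescue | ≤ 300 kb clone, ≥ 10% mutual overlap, sd ≤ 3 cM, mean cM | |
| OM join | Σ best-alignment confidence ≥ 25 per cluster, footprints ≤ 300 kb apart, backbone-vs-OM Spearman > 0.5 | steps 3, 4, 8, 10–12 |
| NR subtraction | ≥ 500 bp, ≥ 99.5% id, ≤ 10 MST hops | |
| Hi-C fragments | intact HindIII ≥ 100 bp, mean depth 7–21× | |
| Hi-C pairs | both mapq ≥ 10, inferred molecule < 500 bp | |
| Hi-C clusters | NR ≥ 30 kb, ≥ 20 fragments, links within 15 cM | |
| PR regions | self-hits ≥ 5 kb, ≥ 99.8% id | masking |

### Numerical and procedural choices

* **MST sense.** Edge weights are cumulative overlap length; the spanning
  tree is computed on *negated* weights so it retains the strongest
  overlaps (configurable). Diameter ties break to the lexicographically
  smallest terminal pair; the path is listed from its smaller terminal.
* **Branch membership.** A "branch" is every off-backbone node of a BAC
  bin whose maximum rank exceeds 1; predicates (non-MTP, gene-bearing,
  length, N50) select which branch members each pruning stage removes.
* **Candidate commits.** Steps 3–12 commit candidate edges one at a time
  in deterministic order (supporting-evidence strength descending, then
  lexicographic pair ids), validating the affected cluster after each
  commit and rolling back offenders. This is equivalent to
  batch-add-then-rollback for independent candidates and resolves
  conflicting candidates deterministically.
* **Cluster ends.** The two diameter termini plus their rank-1
  attachments (termini-only available as an option).
* **Overlap extent per BAC.** Extents are computed and stored per side;
  "≥ X% of the length of either BAC" tests pass if either side passes.
* **Consensus maps.** Primary-on-secondary local regression (lowess,
  span 0.3, locally linear) interpolates secondary-only contigs. The 5 cM
  disagreement test for shared contigs uses leave-one-out interpolation,
  because a curve evaluated at a contig's own point absorbs the outlier
  it is supposed to flag; end points extrapolate from their two nearest
  neighbours.
* **Cluster N50.** Mass-based: the size N such that clusters of at least
  N members contain half of all clustered BACs ({4,3,2,1,1} → 3). Both
  the plain mean cluster size and the BAC-weighted mean (Σs²/Σs) are
  reported, since the two disagree in general.
* **Hi-C weights.** Raw link counts, weight −log₁₀(links); cluster pairs
  with zero links get no edge, and path adjacencies without links are
  charged a fixed penalty of 3.0 (the −log₁₀ of a pseudo-count below one
  link) so insertion and 2-opt remain well-defined. A
  fragment-normalised mode exists but is off by default.
* **2-opt.** Left-to-right sweeps of segment reversals plus single-node
  relocations, accepting only strictly improving moves (asserted per
  move), capped at 100 sweeps.
* **Orientation.** Clusters are divided into bins on their concatenated
  NR sequence; the trailing remainder folds into the last full bin, so no
  bin holds less than one bin-length of sequence (tiny bins carry too few
  restriction fragments to order reliably). All bins of a chromosome are
  ordered by the same Hi-C optimizer; a cluster spanning ≥ 2 bins takes
  the sign of the correlation between its internal bin index and the
  global bin order, corrected for local bin-map inversions by the
  correlation over the window of the cluster and its two ordered
  neighbours. Single-bin clusters fall back to the GBS marker cM
  gradient (≥ 2 markers), else stay unoriented. Rank correlations are
  Spearman throughout.
* **Inferred Hi-C molecule size** is the sum of the two ends' distances
  to their nearest fragment boundary (read orientation is not tracked).
* **Residual-redundancy classes.** (i) chromosome-placed regions hitting
  only other chromosomes; (ii) optional intra-chromosomal analogue with a
  caller-supplied distance threshold (no default is claimed — the
  appropriate distance depends on the map's resolution); (iii) chrUn
  regions hitting chromosomes; (iv) otherwise the copy with the
  lexicographically larger (sequence, start) key. Masking overwrites with
  N and conserves lengths.
* **Initial screen floor.** The bare identity ≥ 90% removal branch is
  applied down to a 100 bp reporting floor, since no aligner reports
  arbitrarily short hits.
* **Splash checks.** Flank 20-mers cluster by single linkage at Hamming
  distance < 3 with per-position majority consensus; the plate-neighbour
  relation is the 8-neighbourhood of the well grid (configurable); pairs
  sharing > 10% of either clone's sequence at ≥ 99% identity are flagged.

## The built-in aligner

A seed-and-extend aligner (exact 31-mer anchors from a sorted-array
k-mer index, chaining along diagonals with a 40 bp gap bound, greedy
ungapped extension) emits 12-column BLAST-tabular HSPs. It is ungapped by
design: every alignment the pipeline consumes is between assemblies of
one genotype at ≥ 99% identity, where indel-free chains dominate. The
40 bp chain bound keeps assembly N-gaps (tens of bp) from being absorbed
into an HSP and diluting its identity, mirroring how a word-based aligner
would split there. K-mers occurring more than 200 times are dropped from
the index (high-copy repeats). Externally produced BLAST tabular files
can be ingested in place of the built-in aligner.

## The synthetic benchmark

`simulate` generates a genome and every evidence layer from one truth
set; all operations are pure functions of (inputs, seed), and the same
seed yields byte-identical outputs.

Default study conditions (a scaled-down analogue of a hierarchical
BAC-by-BAC project): two chromosomes of 1 Mb; BAC length 50 ± 5 kb with
10 kb tiling overlaps; 2–4 scaffolds per BAC with random strands and
occasional internal N-gaps; 15% redundant non-MTP clones; genetic map at
20 cM/Mb with 0.5 cM noise on 5 kb WGS contigs; physical-map (FP) breaks
at 15% per junction, capped at 12 tiles per contig, each break a 0.5–2 kb
unclonable gap; two optical-map contigs per chromosome; BAC-end pairs
from every clone; 10⁵ Hi-C pairs with power-law contact decay (exponent
1), 2% trans pairs, read ends near HindIII sites. Two scale choices
deserve note: 20 cM/Mb keeps the 3 cM pairing window discriminative
(~3 BAC lengths) while genuine cluster spans stay below the 5 cM
cluster-sd ceiling, mirroring the real-genome ratios of these windows to
clone and contig sizes; and the orientation bin size of 50 kb preserves
the published bin-to-cluster size ratio at benchmark cluster sizes.
Chimeric clones (half-and-half inserts from a different chromosome with
probability 0.5, else two loci ≥ 40% of a chromosome apart) and
contaminated clones (insertions from a bundled synthetic vector/host
library) are added at configurable rates as extra clones, so the MTP
still covers the genome and truth conservation holds.

What the generator does **not** emulate: read-level sequencing error and
coverage biases (assemblies are exact genome substrings apart from N-gap
artifacts), misassembly other than chimerism and fragmentation,
segmental-duplication structure beyond exact repeat-family copies,
population-level noise in the genetic maps beyond Gaussian cM jitter, and
optical-map sizing error. Passing tests therefore certify the
*integration logic* — classification thresholds, graph invariants,
subtraction bookkeeping, ordering optimizers, coordinate lifts — not
robustness to assembly error in real data.

Mapping simulated Hi-C pairs onto the reconstructed sequence uses the
truth set's coordinate lift (emulating the short-read aligner, which the
real pipeline consumes rather than runs).

## Benchmark sizes

Tests and the acceptance script run the full pipeline on the
two-chromosome 1 Mb benchmark (~55 clones, ~12 s), the chimera benchmark
on five seeds of the same size, ordering benchmarks on 20 clusters with
10⁵ decay-law pairs plus 100 seven-cluster instances compared against
exhaustive Hamiltonian-path search, and the exact oracles on 1,000 random
interval sets and 100 random ≤ 12-node graphs. The complete suite
finishes in about two minutes on one CPU.

## Known limitations

* The aligner is ungapped; diverged duplications (< 99% identity) are
  invisible to it, which matches the pipeline's thresholds but makes the
  aligner unsuitable as a general-purpose tool.
* Orientation of short clusters (≲ 3 bins) from Hi-C alone is fragile —
  at benchmark scale about 5% of multi-bin clusters come out flipped,
  consistent with the method's known ~100 kb resolution limit; the GBS
  fallback only helps where markers land inside the cluster.
* `merge_consensus_map` treats chromosomes with fewer than 10 shared
  contigs as uninterpolatable and leaves their secondary-only contigs
  unanchored.
* The step-8 FP/OM orientation-consistency check relies on the OM rank
  correlation of each cluster; FP band order is used only for distance,
  not for an independent orientation test.
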