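"""End-to-end integration pipeline over a synthetic dataset.

Runs simulation, contaminant screening, overlap detection, genetic
anchoring, overlap-graph refinement, non-redundant sequence construction,
Hi-C ordering/orientation and pseudomolecule emission, returning every
intermediate product for inspection and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import anchor as anchor_mod
from . import contam, hic, nrseq, overlaps, pseudo, simulate
from .align import align_pairwise, hsps_to_frame
from .graph import (
    OverlapGraph,
    RefinementEvidence,
    meta_from_library,
    run_refinement,
)
from .simulate import BacAssembly, Evidence, Genome, Scaffold, SimConfig, TruthSet

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: SimConfig
    genome: Genome
    library: dict[str, BacAssembly]
    truth: TruthSet
    evidence: Evidence
    overlap_calls: list
    anchors: dict
    graph: OverlapGraph
    step_stats: pd.DataFrame
    clusters: dict[str, list[str]]
    nr: dict[str, str]
    provenance: pd.DataFrame
    nr_layout: pd.DataFrame
    cluster_anchors: dict
    link_counts: hic.LinkCounts | None
    order: pd.DataFrame
    orientations: dict[str, str]
    pseudomolecules: pseudo.PseudomoleculeSet
    extra: dict = field(default_factory=dict)


def screen_library(
    library: dict[str, BacAssembly], truth: TruthSet
) -> dict[str, BacAssembly]:
    """Initial contaminant screen; rebuilds assemblies from the surviving
    scaffold pieces and registers cut pieces in the truth layout."""
    contam_lib = simulate.contaminant_library()
    scaffold_seqs = simulate.library_fasta(library)
    hsps = align_pairwise(
        scaffold_seqs, contam_lib, min_identity=80.0, min_length=100,
        skip_self=False,
    )
    cleaned, removed = contam.screen_initial(scaffold_seqs, hsps_to_frame(hsps))
    out: dict[str, BacAssembly] = {}
    for bac, assembly in library.items():
        layout = {
            sid: (bs, be, st) for sid, bs, be, st in truth.bacs[bac].scaffold_layout
        }
        new_scaffolds = []
        for name, seq in cleaned.items():
            parsed = contam.parse_region(name)
            base, a, b = parsed if parsed else (name, 0, len(seq))
            if overlaps.bac_of(base) != bac:
                continue
            new_scaffolds.append(Scaffold(name, seq))
            if parsed and base in layout:
                bs, be, st = layout[base]
                if st > 0:
                    piece = (name, bs + a, bs + b, st)
                else:
                    piece = (name, be - b, be - a, st)
                truth.bacs[bac].scaffold_layout.append(piece)
        if new_scaffolds:
            out[bac] = BacAssembly(
                bac,
                sorted(new_scaffolds, key=lambda s: s.scaffold_id),
                is_mtp=assembly.is_mtp,
                gene_bearing=assembly.gene_bearing,
                fp_contig=assembly.fp_contig,
                fp_band=assembly.fp_band,
            )
    return out


def run_pipeline(
    config: SimConfig,
    screen: bool = True,
    run_hic: bool = True,
    hic_bin_size: int = 50_000,
    hic_min_len: int = 30_000,
    hic_min_frags: int = 20,
) -> PipelineResult:
    """The full integration pipeline on one synthetic dataset."""
    log.info("simulating genome and evidence (seed=%d)", config.seed)
    genome = simulate.simulate_genome(config)
    library, truth = simulate.simulate_bac_library(genome, config)
    evidence = simulate.simulate_linkage_evidence(genome, library, truth, config)

    if screen:
        library = screen_library(library, truth)

    log.info("aligning %d BAC assemblies all-vs-all", len(library))
    scaffold_seqs = simulate.library_fasta(library)
    hsp_table = overlaps.align_assemblies(scaffold_seqs)
    calls = overlaps.compute_overlaps(hsp_table)

    log.info("anchoring BACs to the genetic map")
    anchors = anchor_mod.anchor_all_bacs(
        evidence.wgs_hits, evidence.wgs_map, sorted(library)
    )
    lengths = {b: a.length for b, a in library.items()}
    anchors = anchor_mod.rescue_via_neighbors(anchors, calls, lengths)

    log.info("building and refining the overlap graph")
    meta = meta_from_library(library)
    ref_ev = RefinementEvidence.build(
        calls, om=evidence.om, bes=evidence.bes,
        wgs_hits=evidence.wgs_hits, wgs_map=evidence.wgs_map,
    )
    og, step_stats = run_refinement(meta, calls, anchors, ref_ev)
    clusters = og.cluster_map()

    log.info("constructing non-redundant sequences for %d components",
             len(clusters))
    nr: dict[str, str] = {}
    prov_frames = []
    layout_rows = []
    cluster_anchors = {}
    backbones = {}
    for cid, members in clusters.items():
        comp = frozenset(members)
        bb = og.backbone(comp) if len(members) > 1 else None
        backbones[cid] = bb
        scaffolds = {b: library[b].sequences() for b in members}
        cluster_nr, prov = nrseq.build_nr(cid, members, scaffolds, bb)
        nr.update(cluster_nr)
        prov_frames.append(prov)
        # fragments in backbone order: order by source BAC's backbone
        # position, then by provenance order within the BAC
        if bb is not None:
            pos = {
                b: (bb.diameter.index(bb.attachment[b]), b)
                for b in members
            }
        else:
            pos = {b: (0, b) for b in members}
        ordered = sorted(
            prov.itertuples(), key=lambda r: (pos[r.bac], r.seq)
        )
        offset = 0
        for r in ordered:
            layout_rows.append((cid, r.seq, offset, r.end - r.start))
            offset += (r.end - r.start) + pseudo.GAP
        cluster_anchors[cid] = og.cluster_anchor(comp) if len(members) > 1 else (
            anchor_mod.ClusterAnchor(
                anchors[members[0]].status
                if anchors[members[0]].status == anchor_mod.ANCHORED
                else anchor_mod.UNANCHORED,
                anchors[members[0]].position,
            )
        )
    provenance = (
        pd.concat(prov_frames, ignore_index=True)
        if prov_frames
        else pd.DataFrame(
            columns=["seq", "start", "end", "bac", "scaffold", "scf_start",
                     "scf_end", "strand"]
        )
    )
    nr_layout = pd.DataFrame(
        layout_rows, columns=["cluster", "seq", "offset", "length"]
    )

    link_counts = None
    order = pd.DataFrame(columns=["chrom", "rank", "cluster", "cm"])
    orientations: dict[str, str] = {}
    if run_hic:
        log.info("tabulating Hi-C links and ordering clusters")
        pairs = simulate.simulate_hic_pairs(genome, config)
        lift = simulate.build_genome_lift(provenance, truth)
        mapped = simulate.map_pairs_to_reference(pairs, lift)
        fragments = hic.digest(nr)
        depth = simulate.simulate_depth_bed(
            {k: len(v) for k, v in nr.items()}, seed=config.seed
        )
        fragments = hic.filter_fragments(fragments, depth)
        seq_cluster = dict(zip(nr_layout["seq"], nr_layout["cluster"]))
        link_counts = hic.count_links(mapped, fragments, seq_cluster)
        nr_lengths = {
            c: int(grp["length"].sum())
            for c, grp in nr_layout.groupby("cluster")
        }
        frag_counts = (
            fragments[fragments["pass"]]
            .assign(cluster=lambda d: d["seq"].map(seq_cluster))
            .groupby("cluster")["seq"]
            .count()
            .to_dict()
        )
        order = hic.order_clusters(
            link_counts, cluster_anchors, nr_lengths, frag_counts,
            min_len=hic_min_len, min_frags=hic_min_frags,
        )
        oriented = hic.orient_clusters(
            order, nr_layout, mapped, fragments, cluster_anchors,
            bin_size=hic_bin_size,
        )
        orientations = dict(zip(oriented["cluster"], oriented["orientation"]))

    placed = set(order["cluster"])
    unplaced = sorted(set(clusters) - placed)
    pset = pseudo.build_pseudomolecules(
        order, orientations, nr, nr_layout, unplaced_clusters=unplaced
    )
    return PipelineResult(
        config, genome, library, truth, evidence, calls, anchors, og,
        step_stats, clusters, nr, provenance, nr_layout, cluster_anchors,
        link_counts, order, orientations, pset,
    )
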