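"""Truth-based evaluation of pipeline output on synthetic data.

These helpers compare reconstructed pseudomolecules against the simulator's
truth set: base-level placement multiplicity, cluster-order recovery,
marker collinearity and chimera handling. They are measurement tools for
benchmarks and tests, not part of the integration pipeline itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import qc, simulate
from .pipeline import PipelineResult


def placement_index(placement: pd.DataFrame) -> dict[str, tuple]:
    """seq -> (chrom, start, end, strand) for placed fragments."""
    return {
        r.seq: (r.chrom, int(r.start), int(r.end), r.strand)
        for r in placement.itertuples()
    }


def pseudo_position(index: dict, seq: str, pos: int) -> tuple[str, int] | None:
    info = index.get(seq)
    if info is None:
        return None
    chrom, start, end, strand = info
    return (chrom, start + pos) if strand == "+" else (chrom, end - 1 - pos)


def genome_placement_stats(result: PipelineResult) -> dict:
    """Fraction of genome bases represented exactly once / more than once
    in the pseudomolecules (chrUn included)."""
    placed_seqs = set(result.pseudomolecules.placement["seq"])
    trees = simulate.build_genome_lift(result.provenance, result.truth)
    total = sum(result.truth.chromosomes.values())
    once = 0
    multi = 0
    for chrom, tree in trees.items():
        events: list[tuple[int, int]] = []
        for iv in tree:
            if iv.data[0] in placed_seqs:
                events.append((iv.begin, 1))
                events.append((iv.end, -1))
        events.sort()
        depth = 0
        prev = 0
        for pos, delta in events:
            if pos > prev:
                if depth == 1:
                    once += pos - prev
                elif depth > 1:
                    multi += pos - prev
            depth += delta
            prev = pos
    return {
        "fraction_once": once / total,
        "fraction_multi": multi / total,
        "fraction_covered": (once + multi) / total,
    }


def true_cluster_positions(result: PipelineResult) -> dict[str, tuple[str, float]]:
    """True (chromosome, median genomic start) per reconstructed cluster."""
    out = {}
    for cid, members in result.clusters.items():
        spans = [
            result.truth.bacs[b].primary_span()
            for b in members
            if b in result.truth.bacs
        ]
        if not spans:
            continue
        chroms = pd.Series([s[0] for s in spans])
        chrom = chroms.mode().iloc[0]
        starts = [s[1] for s in spans if s[0] == chrom]
        out[cid] = (chrom, float(np.median(starts)))
    return out


def order_recovery(result: PipelineResult) -> pd.DataFrame:
    """Kendall tau between recovered and true cluster order per
    chromosome (positive tau = correct polarity)."""
    truth_pos = true_cluster_positions(result)
    rows = []
    for chrom, grp in result.order.groupby("chrom"):
        ordered = list(grp.sort_values("rank")["cluster"])
        pairs = [
            (rank, truth_pos[c][1])
            for rank, c in enumerate(ordered)
            if c in truth_pos and truth_pos[c][0] == chrom
        ]
        if len(pairs) < 2:
            rows.append((chrom, np.nan, len(pairs)))
            continue
        tau = kendalltau([p[0] for p in pairs], [p[1] for p in pairs]).statistic
        rows.append((chrom, float(tau), len(pairs)))
    return pd.DataFrame(rows, columns=["chrom", "tau", "n_clusters"])


def orientation_accuracy(result: PipelineResult, bin_size: int) -> dict:
    """Accuracy of '+'/'-' calls for multi-bin clusters; truth orientation
    of every simulated cluster is '+' after the chromosome-polarity step."""
    nr_len = result.nr_layout.groupby("cluster")["length"].sum().to_dict()
    multi = [
        c
        for c in result.orientations
        if nr_len.get(c, 0) >= 2 * bin_size
    ]
    called = [c for c in multi if result.orientations[c] in "+-"]
    correct = [c for c in called if result.orientations[c] == "+"]
    return {
        "n_multibin": len(multi),
        "n_called": len(called),
        "accuracy": len(correct) / len(called) if called else np.nan,
    }


def marker_collinearity(
    result: PipelineResult, subsample: int = 5
) -> pd.DataFrame:
    """Collinearity of WGS-contig markers between pseudomolecule position
    and genetic map position (per pseudomolecule chromosome)."""
    trees = simulate.build_genome_lift(result.provenance, result.truth)
    index = placement_index(result.pseudomolecules.placement)
    cm_of = dict(
        zip(result.evidence.wgs_map["wgs_contig"], result.evidence.wgs_map["cm"])
    )
    rows = []
    wgs = result.truth.wgs_contigs
    for r in wgs.iloc[::subsample].itertuples():
        mid = (int(r.start) + int(r.end)) // 2
        hit = simulate.lift_position(trees, r.chrom, mid)
        if hit is None:
            continue
        pos = pseudo_position(index, hit[0], hit[1])
        if pos is None or pos[0] == "chrUn":
            continue
        rows.append((r.wgs_contig, pos[0], pos[1], cm_of[r.wgs_contig]))
    positions = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cm"])
    table, _ = qc.collinearity_check(positions)
    return table


def chimera_handling(result: PipelineResult) -> dict:
    """How many planted chimeric BACs were excluded, or at least flagged
    as inconsistently anchored.

    The reinstatement step of the graph refinement may deliberately
    re-admit a flagged single-chromosome chimera when it creates no branch
    (its redundant half is masked later); such clones count as detected
    but not excluded.
    """
    from .anchor import INCONSISTENT

    chimeras = result.truth.chimeric_bacs()
    excluded = [b for b in chimeras if b in result.graph.excluded]
    flagged = [
        b
        for b in chimeras
        if b in result.graph.excluded
        or result.anchors[b].status == INCONSISTENT
    ]
    in_cluster = [
        b
        for b in chimeras
        if result.graph.g.has_node(b) and result.graph.g.degree[b] > 0
    ]
    return {
        "n_chimeric": len(chimeras),
        "n_excluded": len(excluded),
        "n_flagged": len(flagged),
        "n_clustered": len(in_cluster),
        "exclusion_rate": len(excluded) / len(chimeras) if chimeras else np.nan,
        "detection_rate": len(flagged) / len(chimeras) if chimeras else np.nan,
    }
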