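"""Pseudomolecule construction, splitting, residual-redundancy masking and
summary statistics.

A pseudomolecule concatenates the ordered, oriented NR fragments of each
chromosome with fixed 100-N gaps; unplaced sequence goes to chrUn. The
placement BED records every fragment's final coordinates and strand, so
the pseudomolecule can be reconstructed byte-for-byte from the fragment
FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import revcomp
from .intervals import merge_intervals

GAP = 100  # N characters between adjacent sequence fragments
SPLIT_LIMIT = 512_000_000  # SAM/BAM indexing limit on reference length


@dataclass
class PseudomoleculeSet:
    fasta: dict[str, str]
    placement: pd.DataFrame  # chrom, start, end, seq, strand, cluster


def build_pseudomolecules(
    order: pd.DataFrame,
    orientations: dict[str, str],
    nr: dict[str, str],
    nr_layout: pd.DataFrame,
    chrun_pool: dict[str, str] | None = None,
    unplaced_clusters: list[str] | None = None,
) -> PseudomoleculeSet:
    """Emit one record per chromosome plus chrUn.

    ``order``: (chrom, rank, cluster); ``nr_layout``: (cluster, seq, offset,
    length) giving each cluster's fragments in backbone order. A cluster
    with orientation '-' contributes its fragments in reversed order, each
    reverse-complemented. Unplaced clusters and the chrUn pool are
    concatenated on chrUn in lexicographic order (their internal order is
    undetermined).
    """
    frags_of = {
        c: [r.seq for r in grp.sort_values("offset").itertuples()]
        for c, grp in nr_layout.groupby("cluster")
    }
    for r in nr_layout.itertuples():
        if r.seq not in nr:
            raise KeyError(f"fragment {r.seq!r} referenced but missing from NR")
    fasta: dict[str, str] = {}
    rows = []
    for chrom, grp in order.groupby("chrom"):
        parts: list[tuple[str, str, str, str]] = []  # (seq_name, seq, strand, cluster)
        for r in grp.sort_values("rank").itertuples():
            frags = frags_of.get(r.cluster, [])
            strand = orientations.get(r.cluster, "?")
            if strand == "-":
                parts.extend(
                    (name, revcomp(nr[name]), "-", r.cluster)
                    for name in reversed(frags)
                )
            else:
                parts.extend((name, nr[name], "+", r.cluster) for name in frags)
        fasta[chrom], placed = _concat(chrom, parts)
        rows.extend(placed)
    # chrUn
    un_parts: list[tuple[str, str, str, str]] = []
    for c in sorted(unplaced_clusters or []):
        un_parts.extend((name, nr[name], "+", c) for name in frags_of.get(c, []))
    for name in sorted(chrun_pool or {}):
        un_parts.append((name, (chrun_pool or {})[name], "+", "chrUn_pool"))
    if un_parts:
        fasta["chrUn"], placed = _concat("chrUn", un_parts)
        rows.extend(placed)
    placement = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "seq", "strand", "cluster"]
    )
    return PseudomoleculeSet(fasta, placement)


def _concat(chrom: str, parts):
    pieces, rows = [], []
    pos = 0
    for i, (name, seq, strand, cluster) in enumerate(parts):
        if i > 0:
            pieces.append("N" * GAP)
            pos += GAP
        pieces.append(seq)
        rows.append((chrom, pos, pos + len(seq), name, strand, cluster))
        pos += len(seq)
    return "".join(pieces), rows


def reconstruct_from_placement(
    placement: pd.DataFrame, nr: dict[str, str]
) -> dict[str, str]:
    """Rebuild pseudomolecule sequences from the placement BED; the result
    must equal the emitted FASTA byte-for-byte."""
    out = {}
    for chrom, grp in placement.groupby("chrom"):
        grp = grp.sort_values("start")
        pieces = []
        pos = 0
        for r in grp.itertuples():
            if r.start > pos:
                pieces.append("N" * (r.start - pos))
            seq = nr[r.seq]
            pieces.append(revcomp(seq) if r.strand == "-" else seq)
            pos = r.end
        out[chrom] = "".join(pieces)
    return out


def placement_to_agp(placement: pd.DataFrame) -> pd.DataFrame:
    """AGP v2.0 view of the placement plan: W component lines for fragments
    and U gap lines (scaffold gaps, evidence 'map') between them."""
    rows = []
    for chrom, grp in placement.groupby("chrom"):
        grp = grp.sort_values("start")
        part = 0
        prev_end = 0
        for r in grp.itertuples():
            if r.start > prev_end:
                part += 1
                rows.append(
                    (chrom, prev_end + 1, r.start, part, "U",
                     r.start - prev_end, "scaffold", "yes", "map")
                )
            part += 1
            rows.append(
                (chrom, r.start + 1, r.end, part, "W", r.seq, 1,
                 r.end - r.start, r.strand)
            )
            prev_end = r.end
    return pd.DataFrame(
        rows,
        columns=["object", "object_beg", "object_end", "part_number",
                 "component_type", "c1", "c2", "c3", "c4"],
    )


# ---------------------------------------------------------------------------
# splitting


def split_pseudomolecules(
    fasta: dict[str, str],
    placement: pd.DataFrame,
    limit: int = SPLIT_LIMIT,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Split records larger than ``limit`` at the inter-fragment gap nearest
    their midpoint, recursively. Returns (split FASTA, conversion BED) with
    conversion rows (part, part_start, part_end, chrom, start, end)."""
    out: dict[str, str] = {}
    conv_rows = []

    def emit(chrom, seq, offset, part_idx):
        name = chrom if offset == 0 and len(seq) == len(fasta[chrom]) else (
            f"{chrom}_part{part_idx[0]}"
        )
        if name != chrom:
            part_idx[0] += 1
        out[name] = seq
        conv_rows.append((name, 0, len(seq), chrom, offset, offset + len(seq)))

    for chrom, seq in fasta.items():
        grp = placement[placement["chrom"] == chrom].sort_values("start")
        part_idx = [1]

        def split(lo, hi):
            length = hi - lo
            if length <= limit:
                emit(chrom, seq[lo:hi], lo, part_idx)
                return
            # candidate breakpoints: gaps between consecutive fragments
            inner = grp[(grp["start"] >= lo) & (grp["end"] <= hi)]
            ends = inner["end"].to_numpy()
            starts = inner["start"].to_numpy()
            gaps = [
                (int(e), int(s))
                for e, s in zip(ends[:-1], starts[1:])
                if s > e
            ]
            if not gaps:
                raise ValueError(
                    f"cannot split {chrom}: single fragment longer than limit"
                )
            mid = lo + length // 2
            ge, gs = min(gaps, key=lambda g: abs((g[0] + g[1]) // 2 - mid))
            split(lo, ge)
            split(gs, hi)

        split(0, len(seq))
    conversion = pd.DataFrame(
        conv_rows,
        columns=["part", "part_start", "part_end", "chrom", "start", "end"],
    )
    return out, conversion


# ---------------------------------------------------------------------------
# residual-redundancy masking


def mask_residual_redundancy(
    fasta: dict[str, str],
    self_hsps,
    min_length: int = 5_000,
    min_identity: float = 99.8,
    intra_distance: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Mask potentially redundant (PR) regions found by self-alignment.

    PR regions are intervals of hits >= 5 kb at >= 99.8% identity. Classes:
    (i) a chromosome-placed region whose hits all go to other chromosomes
    is masked (inter-chromosomal chimera); (ii) with ``intra_distance``
    set, a region whose same-chromosome hits are all farther than that
    distance is masked (intra-chromosomal chimera); (iii) a chrUn region
    hitting a chromosome is masked; (iv) for remaining redundant pairs the
    copy with the lexicographically larger (sequence, start) key is
    masked. Masking overwrites with N, conserving record lengths.
    """
    qualifying = [
        h
        for h in self_hsps
        if h.length >= min_length and h.identity >= min_identity
        and (h.query, h.query_interval()) != (h.subject, h.subject_interval())
    ]
    # collect PR regions with their partner locations
    regions: list[tuple[str, tuple[int, int], str, tuple[int, int]]] = []
    for h in qualifying:
        regions.append((h.query, h.query_interval(), h.subject,
                        h.subject_interval()))
        regions.append((h.subject, h.subject_interval(), h.query,
                        h.query_interval()))
    partners: dict[tuple[str, tuple[int, int]], list] = {}
    for seq, iv, pseq, piv in regions:
        partners.setdefault((seq, iv), []).append((pseq, piv))
    mask: dict[str, list[tuple[int, int]]] = {}
    masked_regions: set[tuple[str, tuple[int, int]]] = set()
    rows = []

    def do_mask(seq, iv, klass):
        mask.setdefault(seq, []).append(iv)
        masked_regions.add((seq, iv))
        rows.append((seq, iv[0], iv[1], klass))

    for (seq, iv), plist in sorted(partners.items()):
        on_un = seq == "chrUn"
        p_chroms = {p for p, _ in plist}
        if not on_un and all(p != seq and p != "chrUn" for p in p_chroms):
            do_mask(seq, iv, "inter_chromosomal_chimera")
        elif (
            not on_un
            and intra_distance is not None
            and all(p == seq for p in p_chroms)
            and all(
                min(abs(iv[0] - piv[1]), abs(piv[0] - iv[1])) > intra_distance
                for _, piv in plist
            )
        ):
            do_mask(seq, iv, "intra_chromosomal_chimera")
        elif on_un and any(p != "chrUn" for p in p_chroms):
            do_mask(seq, iv, "chrun_redundant")
    # class (iv): unresolved redundant pairs -> mask the larger key
    for h in qualifying:
        a = (h.query, h.query_interval())
        b = (h.subject, h.subject_interval())
        if a in masked_regions or b in masked_regions:
            continue
        victim = max(a, b, key=lambda r: (r[0], r[1][0]))
        do_mask(victim[0], victim[1], "arbitrary_copy")
    masked_fasta = {}
    for name, seq in fasta.items():
        ivs = merge_intervals(mask.get(name, []))
        if not ivs:
            masked_fasta[name] = seq
            continue
        arr = bytearray(seq, "ascii")
        for a, b in ivs:
            arr[a:b] = b"N" * (b - a)
        masked_fasta[name] = arr.decode("ascii")
        assert len(masked_fasta[name]) == len(seq)
    bed = pd.DataFrame(rows, columns=["seq", "start", "end", "class"])
    return masked_fasta, bed


# ---------------------------------------------------------------------------
# summary tables


def add_totals(
    df: pd.DataFrame,
    sum_columns: list[str],
    label_column: str,
    label: str = "total",
) -> pd.DataFrame:
    """Append a totals row (column sums) to a per-chromosome table."""
    totals = {c: df[c].sum() for c in sum_columns}
    totals[label_column] = label
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def pct(part, whole) -> float:
    """Percentage rounded to one decimal, as printed in summary tables."""
    return round(100.0 * part / whole, 1) if whole else float("nan")


def summarize_anchoring(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Anchoring statistics: per chromosome and total counts of sequenced
    and genetically anchored BACs with anchored percentage.

    Input columns: chrom, sequenced, anchored.
    """
    out = add_totals(per_chrom, ["sequenced", "anchored"], "chrom")
    out["anchored_pct"] = [
        pct(a, s) for a, s in zip(out["anchored"], out["sequenced"])
    ]
    return out


def summarize_genetic_map(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Genetic-map statistics (SNP marker map): input columns chrom, snps,
    bins, map_cm. Totals are column sums; cM totals keep one decimal."""
    out = add_totals(per_chrom, ["snps", "bins", "map_cm"], "chrom")
    out["map_cm"] = out["map_cm"].round(1)
    return out


def summarize_wgs_anchoring(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Anchored WGS contig statistics: input columns chrom, contigs,
    length_mb."""
    out = add_totals(per_chrom, ["contigs", "length_mb"], "chrom")
    out["length_mb"] = out["length_mb"].round(1)
    return out


def summarize_clusters(
    cluster_members: dict[str, list[str]],
    cluster_anchors,
    nr_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-chromosome cluster/singleton counts, lengths and length N50."""
    rows = []
    by_chrom: dict[str, list[str]] = {}
    for c, anc in cluster_anchors.items():
        chrom = anc.chrom if anc.status == ANCHORED_STR else "Un"
        by_chrom.setdefault(chrom, []).append(c)
    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        clusters = [c for c in cs if len(cluster_members.get(c, [])) > 1]
        singles = [c for c in cs if len(cluster_members.get(c, [])) == 1]
        lens = sorted((nr_lengths.get(c, 0) for c in cs), reverse=True)
        total = sum(lens)
        n50 = 0
        acc = 0
        for ln in lens:
            acc += ln
            if acc * 2 >= total:
                n50 = ln
                break
        rows.append(
            (
                chrom,
                len(clusters),
                len(singles),
                round(total / 1e6, 1),
                round(sum(nr_lengths.get(c, 0) for c in clusters) / 1e6, 1),
                round(sum(nr_lengths.get(c, 0) for c in singles) / 1e6, 1),
                round(n50 / 1e6, 2),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "clusters", "singletons", "length_mb",
            "length_in_clusters_mb", "length_in_singletons_mb", "n50_mb",
        ],
    )


ANCHORED_STR = "anchored"
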