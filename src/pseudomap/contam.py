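"""Contaminant screening: initial (vector/host), final (uncovered regions vs
a nucleotide-database surrogate) and plate-splash cross-contamination checks.

Sequences are screened against alignment evidence only; this module never
runs an external search tool. When a removal cuts a sequence into pieces,
the pieces are emitted as separate records named ``<name>:<start>-<end>``
(0-based half-open, coordinates in the original record), so that
``output length + removed length == input length`` per input sequence.
"""

from __future__ import annotations

import re
from typing import Callable, Mapping

import pandas as pd

from .align import align_pairwise
from .intervals import merge_intervals, subtract_intervals

#: Hit descriptions matching this pattern are treated as plant-derived and
#: exempt from final-screen removal (case-sensitive alternation of common
#: and taxonomic plant names).
PLANT_NAME_PATTERN = re.compile(
    "Hordeum|Triti|Populus|Aegilops|Avena|Alnus|A\\.squarrosa|Morus|Nelumbo|"
    "Brassica|Cucumis|Citrus|Camelina|Fragaria|Lotus|Tarenaya|Spartina|"
    "Eucommia|Sorghum|Corylus|Theobroma|Phaseolus|Barley|Trifolium|Elymus|"
    "Brachypodium|Beta vulgaris|Ricinus|Licania|Phoenix|H\\.vulgare|Pyrus|"
    "Malus|Prunus|Saccharum|Hypericum|Wheat|Oryza|hloroplast|Secale|Vitis|"
    "Quercus"
)

MIN_KEEP_LENGTH = 500  # discard sequences shorter than this after cutting
MIN_PROPER_NT = 500  # ... or with fewer A/C/G/T characters


def region_name(base: str, start: int, end: int) -> str:
    return f"{base}:{start}-{end}"


def parse_region(name: str) -> tuple[str, int, int] | None:
    """Inverse of :func:`region_name`; None if ``name`` carries no region."""
    m = re.match(r"^(.*):(\d+)-(\d+)$", name)
    if m is None:
        return None
    return m.group(1), int(m.group(2)), int(m.group(3))


def _proper_nt(seq: str) -> int:
    return sum(seq.count(b) for b in "ACGTacgt")


def _cut_sequences(
    sequences: Mapping[str, str], removal: dict[str, list[tuple[int, int]]]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Cut removal intervals out of each sequence; drop short remnants."""
    cleaned: dict[str, str] = {}
    bed_rows = []
    for name, seq in sequences.items():
        cuts = merge_intervals(removal.get(name, []))
        for a, b in cuts:
            bed_rows.append((name, a, b, "removed"))
        kept = subtract_intervals([(0, len(seq))], cuts)
        for a, b in kept:
            piece = seq[a:b]
            if len(piece) < MIN_KEEP_LENGTH or _proper_nt(piece) < MIN_PROPER_NT:
                bed_rows.append((name, a, b, "discarded_short"))
                continue
            out_name = name if (a, b) == (0, len(seq)) else region_name(name, a, b)
            cleaned[out_name] = piece
    bed = pd.DataFrame(bed_rows, columns=["seq", "start", "end", "reason"])
    return cleaned, bed


def screen_initial(
    bac_fastas: Mapping[str, str],
    contaminant_hsps: pd.DataFrame,
    id_only_min_length: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Remove regions aligning to the contaminant library.

    A region is removed if (length >= 500 bp AND identity >= 80%) OR
    identity >= 90%. The bare-identity branch is applied down to the
    aligner's own reporting floor (``id_only_min_length``), since arbitrarily
    short high-identity hits are not reported by any aligner. Sequences left
    with fewer than 500 proper nucleotides (ACGT) or shorter than 500 bp are
    discarded.

    ``contaminant_hsps``: BLAST-tabular frame, query = BAC record.
    """
    removal: dict[str, list[tuple[int, int]]] = {}
    for r in contaminant_hsps.itertuples():
        hit = (float(r.identity), int(r.length))
        if (hit[1] >= 500 and hit[0] >= 80.0) or (
            hit[0] >= 90.0 and hit[1] >= id_only_min_length
        ):
            a, b = int(r.qstart) - 1, int(r.qend)
            removal.setdefault(str(r.query), []).append((a, b))
    return _cut_sequences(bac_fastas, removal)


def uncovered_regions(
    sequences: Mapping[str, str],
    depth_bed: pd.DataFrame,
    min_length: int = 500,
) -> pd.DataFrame:
    """Regions with zero read depth and length >= ``min_length``.

    ``depth_bed``: (seq, start, end, depth) windows. Every sequence must be
    covered by windows; missing sequences raise.
    """
    missing = sorted(set(sequences) - set(depth_bed["seq"].unique()))
    if missing:
        raise ValueError(
            "depth track does not cover sequences: " + ", ".join(missing)
        )
    rows = []
    for name, grp in depth_bed.groupby("seq"):
        if name not in sequences:
            continue
        covered = [
            (int(r.start), int(r.end)) for r in grp.itertuples() if r.depth > 0
        ]
        for a, b in subtract_intervals([(0, len(sequences[name]))], covered):
            if b - a >= min_length:
                rows.append((name, a, b))
    return pd.DataFrame(rows, columns=["seq", "start", "end"])


def screen_final(
    nr_fasta: Mapping[str, str],
    depth_bed: pd.DataFrame,
    nt_hits: pd.DataFrame,
    min_hit_length: int = 100,
    min_hit_identity: float = 80.0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Final contaminant scan of the non-redundant sequence.

    Regions not covered by shotgun reads (>= 500 bp) whose database hits
    (>= 100 bp, >= 80% identity) are NOT plant-annotated are cut out.
    ``nt_hits`` columns: seq, start, end (coordinates on the screened
    sequence), identity, length, subject_desc.
    """
    uncov = uncovered_regions(nr_fasta, depth_bed)
    uncov_ivs: dict[str, list[tuple[int, int]]] = {}
    for r in uncov.itertuples():
        uncov_ivs.setdefault(r.seq, []).append((r.start, r.end))
    removal: dict[str, list[tuple[int, int]]] = {}
    for r in nt_hits.itertuples():
        if int(r.length) < min_hit_length or float(r.identity) < min_hit_identity:
            continue
        if PLANT_NAME_PATTERN.search(str(r.subject_desc)):
            continue
        # only regions inside an uncovered interval are contaminant candidates
        for ua, ub in uncov_ivs.get(str(r.seq), []):
            a, b = max(int(r.start), ua), min(int(r.end), ub)
            if b > a:
                removal.setdefault(str(r.seq), []).append((a, b))
    return _cut_sequences(nr_fasta, removal)


# ---------------------------------------------------------------------------
# splash (well-to-well) contamination


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def cluster_flanks(flanks: list[str], max_dist: int = 3) -> list[str]:
    """Single-linkage clustering of equal-length flank k-mers at Hamming
    distance < ``max_dist``; returns one majority consensus per cluster."""
    if not flanks:
        return []
    L = len(flanks[0])
    for f in flanks:
        if len(f) != L:
            raise ValueError(f"flank length {len(f)} != {L}: all flanks must match")
    clusters: list[list[str]] = []
    for f in flanks:
        placed = False
        for cl in clusters:
            if any(_hamming(f, g) < max_dist for g in cl):
                cl.append(f)
                placed = True
                break
        if not placed:
            clusters.append([f])
    out = []
    for cl in clusters:
        consensus = "".join(
            max("ACGT", key=lambda b: sum(s[i] == b for s in cl)) for i in range(L)
        )
        out.append(consensus)
    return out


def plate_neighbors(
    pos_a: tuple[int, int], pos_b: tuple[int, int]
) -> bool:
    """8-neighbourhood on the plate grid (wells touching horizontally,
    vertically or diagonally)."""
    (ra, ca), (rb, cb) = pos_a, pos_b
    return (ra, ca) != (rb, cb) and abs(ra - rb) <= 1 and abs(ca - cb) <= 1


def splash_check(
    flanks_per_well: Mapping[str, list[str]],
    well_positions: Mapping[str, tuple[int, int]],
    sequences: Mapping[str, Mapping[str, str]],
    flank_length: int = 20,
    consensus_dist: int = 3,
    min_shared_fraction: float = 0.10,
    min_identity: float = 99.0,
    neighbor_fn: Callable[[tuple[int, int], tuple[int, int]], bool] = plate_neighbors,
) -> list[tuple[str, str]]:
    """Flag BAC pairs in neighbouring wells that look cross-contaminated.

    Insert-flank 20-mers are clustered per well (Hamming distance < 3) into
    consensus sequences; wells whose consensus matches a plate neighbour's
    trigger pairwise contig alignment, and pairs sharing more than 10% of
    their sequence at >= 99% identity are flagged (both members).
    """
    consensi = {}
    for well, flanks in flanks_per_well.items():
        for f in flanks:
            if len(f) != flank_length:
                raise ValueError(
                    f"flank of length {len(f)} in well {well}; expected "
                    f"{flank_length}"
                )
        consensi[well] = cluster_flanks(flanks, max_dist=consensus_dist)
    flagged: set[tuple[str, str]] = set()
    wells = sorted(consensi)
    for i, wa in enumerate(wells):
        for wb in wells[i + 1 :]:
            if not neighbor_fn(well_positions[wa], well_positions[wb]):
                continue
            shared = any(
                _hamming(ca, cb) < consensus_dist
                for ca in consensi[wa]
                for cb in consensi[wb]
            )
            if not shared:
                continue
            frac = _shared_fraction(sequences[wa], sequences[wb], min_identity)
            if frac > min_shared_fraction:
                flagged.add((min(wa, wb), max(wa, wb)))
    return sorted(flagged)


def _shared_fraction(
    contigs_a: Mapping[str, str], contigs_b: Mapping[str, str], min_identity: float
) -> float:
    hsps = align_pairwise(
        dict(contigs_a), dict(contigs_b), min_identity=min_identity,
        min_length=500, skip_self=False,
    )
    covered: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        covered.setdefault(h.query, []).append(h.query_interval())
    from .intervals import union_length

    shared_a = sum(union_length(v) for v in covered.values())
    total_a = sum(len(s) for s in contigs_a.values())
    total_b = sum(len(s) for s in contigs_b.values())
    covered_b: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        covered_b.setdefault(h.subject, []).append(h.subject_interval())
    shared_b = sum(union_length(v) for v in covered_b.values())
    return max(
        shared_a / total_a if total_a else 0.0,
        shared_b / total_b if total_b else 0.0,
    )
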