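"""Synthetic genomes, BAC libraries and mapping evidence with known truth.

The generator emulates the inputs of a hierarchical (BAC-by-BAC) genome
assembly project: a multi-chromosome genome is tiled by overlapping BAC
inserts along a minimum tiling path (MTP); each BAC's insert is fragmented
into assembly scaffolds; a physical (fingerprint-contig) map, a cM genetic
map of WGS contigs, optical-map alignments, BAC-end-sequence links, RIL
genotype matrices and Hi-C read pairs are all derived from the same ground
truth, which is retained for recovery tests.

Every operation is a pure function of its inputs and the configured seed;
the same configuration always yields byte-identical outputs.

Coordinates are 0-based half-open throughout. Chromosome labels are
``chr1`` .. ``chrN``; genetic positions are in centimorgan (cM) with a
configurable cM/Mb rate. The physical map uses the fingerprinting scale of
1 consensus band = 1.24 kb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import revcomp

BAND_KB = 1.24  # 1 fingerprint consensus band = 1.24 kb
HINDIII = "AAGCTT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    The defaults describe a small two-chromosome genome (1 Mb per
    chromosome) tiled by ~50 kb BACs — a scaled-down but structurally
    complete analogue of a hierarchical BAC-based assembly project.
    """

    n_chromosomes: int = 2
    chr_length: int = 1_000_000
    repeat_fraction: float = 0.05
    bac_length_mean: int = 50_000
    bac_length_sd: int = 5_000
    tiling_overlap_mean: int = 10_000
    tiling_overlap_sd: float | None = None  # None: mean / 5
    fragments_per_bac: tuple[int, int] = (2, 4)
    chimera_rate: float = 0.01
    contaminant_rate: float = 0.02
    cm_per_mb: float = 20.0
    hic_pairs: int = 100_000
    hic_decay_exponent: float = 1.0
    seed: int = 0
    # secondary knobs (rates and scales of individual evidence layers)
    non_mtp_fraction: float = 0.15
    gene_bearing_fraction: float = 0.2
    fp_break_rate: float = 0.15
    fp_max_run: int = 12  # forced FP break after this many tiles
    fp_gap_range: tuple[int, int] = (500, 2_000)
    cm_noise_sd: float = 0.5
    wgs_contig_length: int = 5_000
    om_contigs_per_chromosome: int = 2
    om_false_rate: float = 0.0
    hic_trans_fraction: float = 0.02
    hic_lowq_fraction: float = 0.05
    hic_min_separation: int = 1_000
    repeat_family_count: int = 5
    repeat_unit_length: int = 2_000
    scaffold_gap_rate: float = 0.3

    def validate(self) -> None:
        rates = {
            "repeat_fraction": self.repeat_fraction,
            "chimera_rate": self.chimera_rate,
            "contaminant_rate": self.contaminant_rate,
            "non_mtp_fraction": self.non_mtp_fraction,
            "fp_break_rate": self.fp_break_rate,
            "hic_trans_fraction": self.hic_trans_fraction,
            "hic_lowq_fraction": self.hic_lowq_fraction,
            "scaffold_gap_rate": self.scaffold_gap_rate,
            "gene_bearing_fraction": self.gene_bearing_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.chr_length < 10 * self.bac_length_mean:
            raise ConfigError(
                "chr_length must be at least 10 x bac_length_mean "
                f"({self.chr_length} < {10 * self.bac_length_mean})"
            )
        if self.tiling_overlap_mean >= self.bac_length_mean:
            raise ConfigError(
                "tiling_overlap_mean must be smaller than bac_length_mean"
            )
        lo, hi = self.fragments_per_bac
        if not (1 <= lo <= hi):
            raise ConfigError("fragments_per_bac must be a (lo, hi) range with lo >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """A deterministic per-operation random generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthSegment:
    """One contiguous piece of a BAC insert, in BAC coordinates."""

    bac_start: int
    bac_end: int
    source: str  # chromosome name, or "contam:<id>"
    ref_start: int
    ref_end: int

    @property
    def is_contaminant(self) -> bool:
        return self.source.startswith("contam:")


@dataclass
class BacTruth:
    bac_id: str
    segments: list[TruthSegment]
    chimeric: bool
    is_mtp: bool
    # (scaffold_id, bac_start, bac_end, strand) in BAC coordinate order
    scaffold_layout: list[tuple[str, int, int, int]] = field(default_factory=list)

    def genome_intervals(self) -> list[tuple[str, int, int]]:
        return [
            (s.source, s.ref_start, s.ref_end)
            for s in self.segments
            if not s.is_contaminant
        ]

    def contaminant_intervals(self) -> list[tuple[int, int]]:
        return [(s.bac_start, s.bac_end) for s in self.segments if s.is_contaminant]

    def primary_span(self) -> tuple[str, int, int]:
        """(chromosome, start, end) of the first genomic segment's locus."""
        g = self.genome_intervals()
        chrom = g[0][0]
        same = [(a, b) for c, a, b in g if c == chrom]
        return chrom, min(a for a, _ in same), max(b for _, b in same)


@dataclass
class TruthSet:
    chromosomes: dict[str, int]
    bacs: dict[str, BacTruth] = field(default_factory=dict)
    # fp contig id -> dict(chrom, start, end, order, members)
    fp_contigs: dict[str, dict] = field(default_factory=dict)
    # true clusters (= non-chimeric BACs grouped by fp contig)
    clusters: dict[str, dict] = field(default_factory=dict)
    # WGS contig truth positions: frame with wgs_contig, chrom, start, end
    wgs_contigs: pd.DataFrame | None = None
    # MTP BACs after which the physical map breaks (a small unclonable gap
    # separates them from the next tile)
    fp_break_after: set[str] = field(default_factory=set)

    def chimeric_bacs(self) -> list[str]:
        return [b for b, t in self.bacs.items() if t.chimeric]

    def scaffold_to_genome(
        self, bac_id: str, scaffold_id: str, a: int, b: int
    ) -> list[tuple[str, int, int, int]]:
        """Map scaffold interval [a, b) to genome pieces.

        Returns (chromosome, gstart, gend, strand) tuples; strand is the
        orientation of the scaffold piece relative to the genome.
        Contaminant-derived pieces are omitted.
        """
        t = self.bacs[bac_id]
        layout = {sid: (bs, be, st) for sid, bs, be, st in t.scaffold_layout}
        bs, be, strand = layout[scaffold_id]
        if strand > 0:
            lo, hi = bs + a, bs + min(b, be - bs)
        else:
            lo, hi = be - min(b, be - bs), be - a
        out = []
        for seg in t.segments:
            if seg.is_contaminant:
                continue
            s = max(lo, seg.bac_start)
            e = min(hi, seg.bac_end)
            if e <= s:
                continue
            out.append(
                (
                    seg.source,
                    seg.ref_start + (s - seg.bac_start),
                    seg.ref_start + (e - seg.bac_start),
                    strand,
                )
            )
        return out

    def to_json(self, path) -> None:
        payload = {
            "chromosomes": self.chromosomes,
            "bacs": {
                b: {
                    "segments": [asdict(s) for s in t.segments],
                    "chimeric": t.chimeric,
                    "is_mtp": t.is_mtp,
                    "scaffold_layout": t.scaffold_layout,
                }
                for b, t in self.bacs.items()
            },
            "fp_contigs": self.fp_contigs,
            "clusters": self.clusters,
            "fp_break_after": sorted(self.fp_break_after),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# contaminant library (bundled, deterministic)


def contaminant_library() -> dict[str, str]:
    """Synthetic stand-ins for cloning-vector / host sequences.

    Generated from a fixed internal seed so the library is identical across
    runs and independent of the simulation seed, mimicking a bundled FASTA.
    """
    rng = np.random.default_rng(424242)
    return {
        name: _random_seq(rng, 5_000)
        for name in ("vector_pBAC", "host_ecoli_frag", "phage_lambda_frag")
    }


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome


@dataclass
class Genome:
    chromosomes: dict[str, str]
    repeat_intervals: dict[str, list[tuple[int, int]]]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}


def simulate_genome(config: SimConfig) -> Genome:
    """Random chromosomes with an optional planted repeat fraction.

    ``repeat_fraction`` of each chromosome is overwritten with copies drawn
    from a small library of repeat families, inducing spurious alignments
    downstream; with ``repeat_fraction=0`` no two windows are identical
    except by chance.
    """
    config.validate()
    rng = config.rng(1)
    repeat_lib = [
        _random_seq(rng, config.repeat_unit_length)
        for _ in range(config.repeat_family_count)
    ]
    chroms: dict[str, str] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    for i in range(config.n_chromosomes):
        name = f"chr{i + 1}"
        arr = bytearray(_random_seq(rng, config.chr_length), "ascii")
        placed: list[tuple[int, int]] = []
        target = config.repeat_fraction * config.chr_length
        covered = 0
        while covered < target:
            unit = repeat_lib[int(rng.integers(len(repeat_lib)))]
            if rng.random() < 0.5:
                unit = revcomp(unit)
            pos = int(rng.integers(0, config.chr_length - len(unit)))
            arr[pos : pos + len(unit)] = unit.encode("ascii")
            placed.append((pos, pos + len(unit)))
            covered += len(unit)
        chroms[name] = arr.decode("ascii")
        repeats[name] = placed
    return Genome(chroms, repeats)


# ---------------------------------------------------------------------------
# BAC library


@dataclass
class Scaffold:
    scaffold_id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BacAssembly:
    bac_id: str
    scaffolds: list[Scaffold]
    is_mtp: bool = True
    gene_bearing: bool = False
    fp_contig: str | None = None
    fp_band: float | None = None

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    @property
    def n50(self) -> int:
        lengths = sorted((len(s) for s in self.scaffolds), reverse=True)
        total = sum(lengths)
        acc = 0
        for ln in lengths:
            acc += ln
            if acc * 2 >= total:
                return ln
        return 0

    def sequences(self) -> dict[str, str]:
        return {s.scaffold_id: s.seq for s in self.scaffolds}


def _draw_bac_length(rng, config: SimConfig) -> int:
    ln = int(rng.normal(config.bac_length_mean, config.bac_length_sd))
    return max(ln, config.tiling_overlap_mean + 5_000, 10_000)


def mtp_tile_count(chr_length: int, bac_length: int, overlap: int) -> int:
    """Closed-form number of MTP BACs tiling a chromosome with fixed BAC
    length and fixed adjacent overlap: ceil((G - L) / (L - o)) + 1."""
    step = bac_length - overlap
    return int(np.ceil((chr_length - bac_length) / step)) + 1


def simulate_bac_library(
    genome: Genome, config: SimConfig
) -> tuple[dict[str, BacAssembly], TruthSet]:
    """Tile each chromosome with a minimum tiling path of BAC inserts and
    add redundant, chimeric and contaminated clones.

    Chimeric BACs concatenate two unlinked loci — a different chromosome
    with probability 0.5 (when more than one exists), otherwise two distant
    loci of the same chromosome — emulating clone cross-contamination.
    Contaminated BACs receive an insertion from the bundled contaminant
    library. Every event is recorded in the returned truth set.
    """
    config.validate()
    rng = config.rng(2)
    truth = TruthSet(chromosomes=genome.lengths())
    library: dict[str, BacAssembly] = {}
    contam = contaminant_library()
    serial = 0

    def new_bac_id() -> str:
        nonlocal serial
        serial += 1
        return f"bac_{serial:05d}"

    def add_bac(pieces: list[tuple[str, int, int]], is_mtp: bool, chimeric: bool):
        """pieces: (source, ref_start, ref_end); source may be a chromosome
        or a contaminant library id prefixed with 'contam:'."""
        bac_id = new_bac_id()
        segs: list[TruthSegment] = []
        seq_parts: list[str] = []
        cursor = 0
        for source, a, b in pieces:
            if source.startswith("contam:"):
                part = contam[source.split(":", 1)[1]][a:b]
            else:
                part = genome.chromosomes[source][a:b]
            segs.append(TruthSegment(cursor, cursor + len(part), source, a, b))
            seq_parts.append(part)
            cursor += len(part)
        bac_seq = "".join(seq_parts)
        # fragment into scaffolds
        lo, hi = config.fragments_per_bac
        n_frag = int(rng.integers(lo, hi + 1))
        cuts = sorted(
            int(p) for p in rng.integers(2_000, max(len(bac_seq) - 2_000, 2_001),
                                         size=max(n_frag - 1, 0))
        )
        cuts = [c for i, c in enumerate(cuts) if i == 0 or c - cuts[i - 1] >= 2_000]
        bounds = [0] + cuts + [len(bac_seq)]
        scaffolds: list[Scaffold] = []
        layout: list[tuple[str, int, int, int]] = []
        for j in range(len(bounds) - 1):
            a, b = bounds[j], bounds[j + 1]
            strand = 1 if rng.random() < 0.5 else -1
            part = bac_seq[a:b] if strand > 0 else revcomp(bac_seq[a:b])
            arr = bytearray(part, "ascii")
            if len(arr) > 400 and rng.random() < config.scaffold_gap_rate:
                gpos = int(rng.integers(150, len(arr) - 150))
                glen = int(rng.integers(20, 81))
                arr[gpos : gpos + glen] = b"N" * min(glen, len(arr) - gpos)
            sid = f"{bac_id}.s{j + 1}"
            scaffolds.append(Scaffold(sid, arr.decode("ascii")))
            layout.append((sid, a, b, strand))
        library[bac_id] = BacAssembly(
            bac_id,
            scaffolds,
            is_mtp=is_mtp,
            gene_bearing=bool(rng.random() < config.gene_bearing_fraction),
        )
        truth.bacs[bac_id] = BacTruth(bac_id, segs, chimeric, is_mtp, layout)
        return bac_id

    def genome_piece(chrom: str, start: int, length: int):
        end = min(start + length, truth.chromosomes[chrom])
        return (chrom, start, end)

    # 1. minimum tiling path per chromosome; physical-map breaks insert a
    # small unclonable gap, so sequence overlaps never span FP contigs
    chrom_names = list(genome.chromosomes)
    glo, ghi = config.fp_gap_range
    for chrom in chrom_names:
        G = truth.chromosomes[chrom]
        start = 0
        run_len = 0
        prev_bac, prev_end = None, 0
        while True:
            length = _draw_bac_length(rng, config)
            if start + length >= G:
                start = max(G - length, 0)
                add_bac([genome_piece(chrom, start, length)], True, False)
                # the clamped final tile may reach back across a recorded
                # break; a clone spanning it means the map has no break there
                if prev_bac in truth.fp_break_after and start < prev_end:
                    truth.fp_break_after.discard(prev_bac)
                break
            bac_id = add_bac([genome_piece(chrom, start, length)], True, False)
            prev_bac, prev_end = bac_id, start + length
            run_len += 1
            if rng.random() < config.fp_break_rate or run_len >= config.fp_max_run:
                truth.fp_break_after.add(bac_id)
                run_len = 0
                start = start + length + int(rng.integers(glo, ghi + 1))
            else:
                sd = (
                    config.tiling_overlap_sd
                    if config.tiling_overlap_sd is not None
                    else config.tiling_overlap_mean / 5
                )
                overlap = int(
                    np.clip(
                        rng.normal(config.tiling_overlap_mean, sd),
                        500,
                        length - 1_000,
                    )
                )
                start = start + length - overlap

    n_mtp = len(library)

    # 2. redundant non-MTP clones
    n_extra = int(round(config.non_mtp_fraction * n_mtp))
    for _ in range(n_extra):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = _draw_bac_length(rng, config)
        start = int(rng.integers(0, max(truth.chromosomes[chrom] - length, 1)))
        add_bac([genome_piece(chrom, start, length)], False, False)

    # 3. chimeric clones (extra clones so the MTP still covers the genome)
    n_chim = int(rng.binomial(len(library), config.chimera_rate))
    for _ in range(n_chim):
        length = _draw_bac_length(rng, config)
        half = length // 2
        c1 = chrom_names[int(rng.integers(len(chrom_names)))]
        s1 = int(rng.integers(0, max(truth.chromosomes[c1] - half, 1)))
        if len(chrom_names) > 1 and rng.random() < 0.5:
            c2 = c1
            while c2 == c1:
                c2 = chrom_names[int(rng.integers(len(chrom_names)))]
            s2 = int(rng.integers(0, max(truth.chromosomes[c2] - half, 1)))
        else:
            # distant loci on one chromosome: at least 40% of the
            # chromosome apart, so the two halves are genetically unlinked
            c2 = c1
            G = truth.chromosomes[c1]
            min_sep = min(int(0.4 * G), G - half - 1)
            while True:
                s2 = int(rng.integers(0, max(G - half, 1)))
                if abs(s2 - s1) >= min_sep:
                    break
        add_bac([genome_piece(c1, s1, half), genome_piece(c2, s2, half)], False, True)

    # 4. contaminant insertions
    contam_ids = list(contam)
    for bac_id in list(library):
        if rng.random() >= config.contaminant_rate:
            continue
        t = truth.bacs[bac_id]
        cid = contam_ids[int(rng.integers(len(contam_ids)))]
        clen = int(rng.integers(1_000, 3_000))
        cstart = int(rng.integers(0, len(contam[cid]) - clen))
        # insert at a random segment boundary-free position of the BAC
        bac_len = t.segments[-1].bac_end
        at = int(rng.integers(5_000, max(bac_len - 5_000, 5_001)))
        _insert_contaminant(library, truth, bac_id, genome, contam, cid,
                            cstart, cstart + clen, at, rng, config)

    if config.contaminant_rate >= 1.0:
        assert all(truth.bacs[b].contaminant_intervals() for b in library)
    return library, truth


def _insert_contaminant(library, truth, bac_id, genome, contam, cid, ca, cb,
                        at, rng, config) -> None:
    """Rebuild a BAC with a contaminant slice inserted at BAC position
    ``at``, refreshing its scaffolds and truth record."""
    t = truth.bacs[bac_id]
    new_pieces: list[tuple[str, int, int]] = []
    for seg in t.segments:
        if seg.bac_start <= at < seg.bac_end:
            off = at - seg.bac_start
            if off > 0:
                new_pieces.append((seg.source, seg.ref_start, seg.ref_start + off))
            new_pieces.append((f"contam:{cid}", ca, cb))
            new_pieces.append((seg.source, seg.ref_start + off, seg.ref_end))
        else:
            new_pieces.append((seg.source, seg.ref_start, seg.ref_end))
    # rebuild sequence/scaffolds deterministically
    segs: list[TruthSegment] = []
    seq_parts: list[str] = []
    cursor = 0
    for source, a, b in new_pieces:
        if source.startswith("contam:"):
            part = contam[source.split(":", 1)[1]][a:b]
        else:
            part = genome.chromosomes[source][a:b]
        segs.append(TruthSegment(cursor, cursor + len(part), source, a, b))
        seq_parts.append(part)
        cursor += len(part)
    bac_seq = "".join(seq_parts)
    old = library[bac_id]
    # keep previous fragmentation cut pattern (scaled to new length)
    n_frag = max(len(old.scaffolds), 1)
    cuts = sorted(
        int(p) for p in rng.integers(2_000, max(len(bac_seq) - 2_000, 2_001),
                                     size=n_frag - 1)
    )
    cuts = [c for i, c in enumerate(cuts) if i == 0 or c - cuts[i - 1] >= 2_000]
    bounds = [0] + cuts + [len(bac_seq)]
    scaffolds: list[Scaffold] = []
    layout: list[tuple[str, int, int, int]] = []
    for j in range(len(bounds) - 1):
        a, b = bounds[j], bounds[j + 1]
        strand = 1 if rng.random() < 0.5 else -1
        part = bac_seq[a:b] if strand > 0 else revcomp(bac_seq[a:b])
        sid = f"{bac_id}.s{j + 1}"
        scaffolds.append(Scaffold(sid, part))
        layout.append((sid, a, b, strand))
    library[bac_id] = BacAssembly(
        bac_id, scaffolds, is_mtp=old.is_mtp, gene_bearing=old.gene_bearing
    )
    truth.bacs[bac_id] = BacTruth(bac_id, segs, t.chimeric, t.is_mtp, layout)


# ---------------------------------------------------------------------------
# linkage evidence


@dataclass
class Evidence:
    """All mapping evidence layers consumed by the integration pipeline."""

    fpc: pd.DataFrame  # bac, fp_contig, band_start, band_end
    wgs_map: pd.DataFrame  # wgs_contig, chrom, cm
    wgs_hits: pd.DataFrame  # wgs_contig, bac
    om: pd.DataFrame  # bac, scaffold, om_contig, om_pos, orientation, confidence
    bes: pd.DataFrame  # bes_pair, mate, bac, pos
    genotypes: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)


def simulate_linkage_evidence(
    genome: Genome,
    library: dict[str, BacAssembly],
    truth: TruthSet,
    config: SimConfig,
) -> Evidence:
    """Derive FP contigs, a WGS-contig genetic map, WGS-to-BAC hits, optical
    map alignments, BAC-end-sequence links and RIL genotype matrices from
    the truth set. Also annotates each BAC with its FP contig assignment."""
    rng = config.rng(3)
    chrom_names = list(genome.chromosomes)

    # --- FP contigs: runs of consecutive MTP BACs, broken stochastically
    fp_rows = []
    fp_serial = 0
    for chrom in chrom_names:
        mtp = sorted(
            (
                (truth.bacs[b].primary_span()[1], b)
                for b in library
                if truth.bacs[b].is_mtp
                and truth.bacs[b].primary_span()[0] == chrom
            )
        )
        runs: list[list[str]] = [[]]
        for i, (_, b) in enumerate(mtp):
            runs[-1].append(b)
            if i < len(mtp) - 1 and b in truth.fp_break_after:
                runs.append([])
        for order, run in enumerate(r for r in runs if r):
            fp_serial += 1
            fp_id = f"fp_{fp_serial:04d}"
            span_start = truth.bacs[run[0]].primary_span()[1]
            span_end = max(truth.bacs[b].primary_span()[2] for b in run)
            truth.fp_contigs[fp_id] = {
                "chrom": chrom,
                "start": span_start,
                "end": span_end,
                "order": order,
                "members": list(run),
            }
            for b in run:
                _, s, e = truth.bacs[b].primary_span()
                library[b].fp_contig = fp_id
                library[b].fp_band = (s - span_start) / (BAND_KB * 1000)
                fp_rows.append(
                    (
                        b,
                        fp_id,
                        (s - span_start) / (BAND_KB * 1000),
                        (e - span_start) / (BAND_KB * 1000),
                    )
                )
    # non-MTP / chimeric clones: assigned to the FP contig containing their
    # primary locus (fingerprinting sees the physical clone)
    fp_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}
    for fp_id, info in truth.fp_contigs.items():
        fp_trees[info["chrom"]].addi(info["start"], max(info["end"], info["start"] + 1),
                                     fp_id)
    for b, assembly in library.items():
        if assembly.fp_contig is not None:
            continue
        chrom, s, e = truth.bacs[b].primary_span()
        mid = (s + e) // 2
        hits = fp_trees[chrom][mid]
        if not hits:
            continue
        fp_id = sorted(iv.data for iv in hits)[0]
        info = truth.fp_contigs[fp_id]
        assembly.fp_contig = fp_id
        assembly.fp_band = (s - info["start"]) / (BAND_KB * 1000)
        fp_rows.append(
            (
                b,
                fp_id,
                (s - info["start"]) / (BAND_KB * 1000),
                (e - info["start"]) / (BAND_KB * 1000),
            )
        )
        if not truth.bacs[b].chimeric:
            info["members"].append(b)
    fpc = pd.DataFrame(fp_rows, columns=["bac", "fp_contig", "band_start", "band_end"])

    # --- true clusters = FP contig membership (chimeras excluded)
    for fp_id, info in truth.fp_contigs.items():
        truth.clusters[fp_id] = {
            "chrom": info["chrom"],
            "order": info["order"],
            "start": info["start"],
            "end": info["end"],
            "members": sorted(info["members"]),
        }

    # --- WGS contigs tiling the genome, with noisy cM positions
    wgs_rows = []
    for chrom in chrom_names:
        G = truth.chromosomes[chrom]
        n = G // config.wgs_contig_length
        for i in range(n):
            a = i * config.wgs_contig_length
            b = min(a + config.wgs_contig_length, G)
            cm = ((a + b) / 2) / 1e6 * config.cm_per_mb
            cm += rng.normal(0.0, config.cm_noise_sd) if config.cm_noise_sd else 0.0
            wgs_rows.append((f"wgs_{chrom}_{i:05d}", chrom, a, b, max(cm, 0.0)))
    wgs = pd.DataFrame(wgs_rows, columns=["wgs_contig", "chrom", "start", "end", "cm"])
    truth.wgs_contigs = wgs[["wgs_contig", "chrom", "start", "end"]].copy()
    wgs_map = wgs[["wgs_contig", "chrom", "cm"]].copy()

    # --- WGS-contig -> BAC alignment hits (>= 1 kb of true overlap)
    wgs_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}
    for r in wgs.itertuples():
        wgs_trees[r.chrom].addi(r.start, r.end, r.wgs_contig)
    hit_rows = []
    for b, t in truth.bacs.items():
        for chrom, a, e in t.genome_intervals():
            for iv in wgs_trees[chrom].overlap(a, e):
                if min(e, iv.end) - max(a, iv.begin) >= 1_000:
                    hit_rows.append((iv.data, b))
    wgs_hits = pd.DataFrame(sorted(set(hit_rows)), columns=["wgs_contig", "bac"])

    # --- optical map: contiguous OM contigs per chromosome; per-scaffold
    # best alignments with confidence scores and optional false joins
    om_bounds: dict[str, list[tuple[int, int, str]]] = {}
    om_serial = 0
    for chrom in chrom_names:
        G = truth.chromosomes[chrom]
        k = max(config.om_contigs_per_chromosome, 1)
        edges = np.linspace(0, G, k + 1).astype(int)
        bounds = []
        for j in range(k):
            om_serial += 1
            bounds.append((int(edges[j]), int(edges[j + 1]), f"om_{om_serial:03d}"))
        om_bounds[chrom] = bounds
    all_om = [om_id for blist in om_bounds.values() for (_, _, om_id) in blist]
    om_rows = []
    for b, assembly in library.items():
        t = truth.bacs[b]
        for sid, bs, be, strand in t.scaffold_layout:
            pieces = truth.scaffold_to_genome(b, sid, 0, be - bs)
            if not pieces:
                continue
            chrom, gs, ge, pstrand = max(pieces, key=lambda p: p[2] - p[1])
            mid = (gs + ge) // 2
            om_id, om_start = None, 0
            for a, e, oid in om_bounds[chrom]:
                if a <= mid < e:
                    om_id, om_start = oid, a
                    break
            if om_id is None:
                continue
            if config.om_false_rate and rng.random() < config.om_false_rate:
                om_id = all_om[int(rng.integers(len(all_om)))]
            conf = float(np.clip((ge - gs) / 1_000, 1.0, 20.0))
            om_rows.append((b, sid, om_id, mid - om_start, pstrand, conf))
    om = pd.DataFrame(
        om_rows,
        columns=["bac", "scaffold", "om_contig", "om_pos", "orientation", "confidence"],
    )

    # --- BAC end sequences: both ends of every clone, hit against all BACs
    # whose true span contains the end locus
    bac_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}
    for b, t in truth.bacs.items():
        if t.chimeric:
            continue
        chrom, s, e = t.primary_span()
        bac_trees[chrom].addi(s, e, b)
    bes_rows = []
    for b, t in truth.bacs.items():
        if t.chimeric:
            continue
        chrom, s, e = t.primary_span()
        for mate, lo, hi in (("L", s, s + 500), ("R", e - 500, e)):
            for iv in bac_trees[chrom].overlap(lo, hi):
                if iv.data == b:
                    continue
                if iv.begin <= lo and iv.end >= hi:
                    bes_rows.append((f"bes_{b}", mate, iv.data, lo - iv.begin))
    bes = pd.DataFrame(bes_rows, columns=["bes_pair", "mate", "bac", "pos"])

    # --- RIL genotype matrices for the map-filtering profiles
    genotypes = {
        "popseq": simulate_genotype_matrix(
            wgs_map, n_samples=40, missing_rate=0.5, het_rate=0.02,
            depth_mean=1.5, rng=config.rng(4),
        ),
        "gbs": simulate_genotype_matrix(
            wgs_map, n_samples=60, missing_rate=0.2, het_rate=0.05,
            depth_mean=8.0, rng=config.rng(5),
        ),
    }
    return Evidence(fpc, wgs_map, wgs_hits, om, bes, genotypes)


def simulate_genotype_matrix(
    marker_map: pd.DataFrame,
    n_samples: int,
    missing_rate: float,
    het_rate: float,
    depth_mean: float,
    rng: np.random.Generator,
    error_rate: float = 0.005,
) -> dict[str, pd.DataFrame]:
    """Markov recombination model along each chromosome's cM map.

    Returns ``calls`` (0=ref hom, 1=het, 2=alt hom, -1=missing), ``depth``
    and ``qual`` frames (markers x samples), plus per-variant ``site_qual``.
    Recombination between adjacent markers follows Haldane's map function
    on the cM distance.
    """
    markers = marker_map.sort_values(["chrom", "cm"]).reset_index(drop=True)
    m = len(markers)
    calls = np.zeros((m, n_samples), dtype=np.int8)
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        d = np.diff(grp["cm"].to_numpy())
        r = 0.5 * (1.0 - np.exp(-2.0 * np.abs(d) / 100.0))
        state = rng.integers(0, 2, n_samples)
        calls[idx[0]] = state * 2
        for j in range(1, idx.size):
            flip = rng.random(n_samples) < r[j - 1]
            state = np.where(flip, 1 - state, state)
            calls[idx[j]] = state * 2
    het = rng.random((m, n_samples)) < het_rate
    calls[het] = 1
    err = rng.random((m, n_samples)) < error_rate
    calls[err] = 2 - calls[err]
    miss = rng.random((m, n_samples)) < missing_rate
    calls[miss] = -1
    depth = rng.poisson(depth_mean, (m, n_samples))
    depth[calls == -1] = 0
    qual = np.clip(rng.normal(30 * np.minimum(depth, 4) / 4, 5), 0, 60).astype(int)
    site_qual = np.clip(rng.normal(120, 40, m), 0, None)
    cols = [f"ril_{i + 1:03d}" for i in range(n_samples)]
    midx = markers["wgs_contig"]
    return {
        "calls": pd.DataFrame(calls, index=midx, columns=cols),
        "depth": pd.DataFrame(depth, index=midx, columns=cols),
        "qual": pd.DataFrame(qual, index=midx, columns=cols),
        "site_qual": pd.Series(site_qual, index=midx, name="site_qual"),
        "map": markers,
    }


# ---------------------------------------------------------------------------
# Hi-C


def sample_power_law(
    rng: np.random.Generator, n: int, alpha: float, d_min: float, d_max: float
) -> np.ndarray:
    """Inverse-CDF sampling from P(d) proportional to d^(-alpha) on
    [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-9:
        return d_min * (d_max / d_min) ** u
    a = 1.0 - alpha
    return (d_min**a + u * (d_max**a - d_min**a)) ** (1.0 / a)


def simulate_hic_pairs(genome: Genome, config: SimConfig) -> pd.DataFrame:
    """Hi-C read pairs in genome coordinates.

    Intra-chromosomal separations follow a power-law contact decay with the
    configured exponent; a configurable fraction of pairs is
    trans-chromosomal. Because proximity-ligation junctions form at
    restriction sites, each read end is placed close to a HindIII cut site
    (exponentially distributed offset, mean ~120 bp). Each end carries a
    mapping quality and its distance to the nearest cut site.
    """
    rng = config.rng(6)
    cut_sites = {
        c: _motif_positions(s, HINDIII) for c, s in genome.chromosomes.items()
    }
    if all(len(v) == 0 for v in cut_sites.values()):
        raise ValueError("no restriction fragments: genome has no HindIII sites")
    chroms = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    n = config.hic_pairs
    is_trans = (rng.random(n) < config.hic_trans_fraction) & (len(chroms) > 1)
    ci1 = rng.choice(len(chroms), n, p=p)
    ci2 = ci1.copy()
    pos1 = (rng.random(n) * lengths[ci1]).astype(np.int64)
    # cis: power-law separation
    d = sample_power_law(
        rng, n, config.hic_decay_exponent, config.hic_min_separation,
        float(lengths.max()) / 2,
    ).astype(np.int64)
    sign = np.where(rng.random(n) < 0.5, 1, -1)
    pos2 = pos1 + sign * d
    # reflect out-of-bounds back inside
    L1 = lengths[ci1].astype(np.int64)
    pos2 = np.abs(pos2)
    pos2 = np.where(pos2 >= L1, 2 * L1 - 2 - pos2, pos2)
    pos2 = np.clip(pos2, 0, L1 - 1)
    # trans: uniform on another chromosome
    if is_trans.any():
        k = int(is_trans.sum())
        shift = rng.integers(1, len(chroms), k)
        ci2[is_trans] = (ci1[is_trans] + shift) % len(chroms)
        pos2[is_trans] = (rng.random(k) * lengths[ci2[is_trans]]).astype(np.int64)
    # snap ends to the neighbourhood of the nearest cut site
    def snap(ci, pos):
        out = pos.copy()
        for idx, c in enumerate(chroms):
            mask = ci == idx
            sites = cut_sites[c]
            if not mask.any() or sites.size == 0:
                continue
            p = pos[mask]
            j = np.clip(np.searchsorted(sites, p), 0, sites.size - 1)
            j_prev = np.clip(j - 1, 0, sites.size - 1)
            nearer = np.where(
                np.abs(sites[j] - p) < np.abs(p - sites[j_prev]), j, j_prev
            )
            offset = (rng.exponential(120, p.size)
                      * np.where(rng.random(p.size) < 0.5, 1, -1))
            out[mask] = np.clip(
                sites[nearer] + offset.astype(np.int64), 0,
                len(genome.chromosomes[c]) - 1,
            )
        return out

    pos1 = snap(ci1, pos1)
    pos2 = snap(ci2, pos2)
    mapq1 = np.where(rng.random(n) < config.hic_lowq_fraction,
                     rng.integers(0, 10, n), 60)
    mapq2 = np.where(rng.random(n) < config.hic_lowq_fraction,
                     rng.integers(0, 10, n), 60)
    df = pd.DataFrame(
        {
            "chrom1": [chroms[i] for i in ci1],
            "pos1": pos1,
            "mapq1": mapq1,
            "chrom2": [chroms[i] for i in ci2],
            "pos2": pos2,
            "mapq2": mapq2,
        }
    )
    for side in ("1", "2"):
        dist = np.empty(n, dtype=np.int64)
        for c in chroms:
            mask = (df[f"chrom{side}"] == c).to_numpy()
            if not mask.any():
                continue
            sites = cut_sites[c]
            if sites.size == 0:
                dist[mask] = 10**9
                continue
            pp = df.loc[mask, f"pos{side}"].to_numpy()
            j = np.searchsorted(sites, pp)
            left = np.abs(pp - sites[np.clip(j - 1, 0, sites.size - 1)])
            right = np.abs(sites[np.clip(j, 0, sites.size - 1)] - pp)
            dist[mask] = np.minimum(left, right)
        df[f"cut_dist{side}"] = dist
    return df


def _motif_positions(seq: str, motif: str) -> np.ndarray:
    out = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        out.append(i)
        start = i + 1
    return np.asarray(out, dtype=np.int64)


def simulate_cluster_links(
    n_clusters: int,
    cluster_span: int,
    n_pairs: int,
    decay_exponent: float = 1.0,
    seed: int = 0,
    d_min: int = 1_000,
) -> tuple[dict[tuple[str, str], int], list[str]]:
    """Cluster-level Hi-C link counts along one synthetic chromosome.

    ``n_clusters`` adjacent spans of ``cluster_span`` bp tile the
    chromosome; ``n_pairs`` read pairs are drawn with power-law contact
    decay and binned by the spans of their two ends. Returns (link counts
    keyed by sorted cluster-id pairs, true cluster order). A fast
    arithmetic shortcut for ordering benchmarks that do not need
    read-level bookkeeping.
    """
    rng = np.random.default_rng([seed % (2**31), 8])
    L = n_clusters * cluster_span
    pos1 = rng.integers(0, L, n_pairs)
    d = sample_power_law(rng, n_pairs, decay_exponent, d_min, L / 2).astype(
        np.int64
    )
    sign = np.where(rng.random(n_pairs) < 0.5, 1, -1)
    pos2 = np.abs(pos1 + sign * d)
    pos2 = np.where(pos2 >= L, 2 * L - 2 - pos2, pos2)
    c1 = pos1 // cluster_span
    c2 = pos2 // cluster_span
    names = [f"cl_{i:03d}" for i in range(n_clusters)]
    links: dict[tuple[str, str], int] = {}
    for a, b in zip(c1, c2):
        if a == b:
            continue
        key = (names[min(a, b)], names[max(a, b)])
        links[key] = links.get(key, 0) + 1
    return links, names


# ---------------------------------------------------------------------------
# mapping simulated reads onto the reconstructed reference (plumbing that
# emulates a short-read aligner, which the pipeline consumes, not runs)


def build_genome_lift(provenance: pd.DataFrame, truth: TruthSet):
    """Interval trees mapping genome coordinates to positions on the
    reconstructed sequences.

    ``provenance`` rows describe reconstructed intervals:
    (seq, start, end, bac, scaffold, scf_start, scf_end, strand).
    Returns dict chrom -> IntervalTree of (gstart, gend, (seq, tpos, step)).
    """
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in truth.chromosomes}
    for r in provenance.itertuples():
        t = truth.bacs[r.bac]
        layout = {sid: (bs, be, st) for sid, bs, be, st in t.scaffold_layout}
        bs, be, sstrand = layout[r.scaffold]
        # BAC-coordinate interval covered by this reconstructed fragment
        if sstrand > 0:
            ylo, yhi = bs + r.scf_start, bs + r.scf_end
        else:
            ylo, yhi = be - r.scf_end, be - r.scf_start
        for seg in t.segments:
            if seg.is_contaminant:
                continue
            s = max(ylo, seg.bac_start)
            e = min(yhi, seg.bac_end)
            if e <= s:
                continue
            gs = seg.ref_start + (s - seg.bac_start)
            ge = seg.ref_start + (e - seg.bac_start)
            if sstrand > 0:
                # genome g -> scaffold x = (g - gs) + (s - bs)
                base = r.start + (s - bs - r.scf_start)
                trees[seg.source].addi(gs, ge, (r.seq, base, 1))
            else:
                # genome g -> scaffold x = (be - 1 - s) - (g - gs)
                base = r.start + (be - 1 - s - r.scf_start)
                trees[seg.source].addi(gs, ge, (r.seq, base, -1))
    return trees


def lift_position(trees, chrom: str, pos: int) -> tuple[str, int] | None:
    hits = trees.get(chrom, IntervalTree())[pos]
    if not hits:
        return None
    iv = min(hits, key=lambda iv: (iv.end - iv.begin, iv.data[0]))
    seq, tpos, step = iv.data
    return seq, tpos + step * (pos - iv.begin)


def map_pairs_to_reference(pairs: pd.DataFrame, trees) -> pd.DataFrame:
    """Lift genome-coordinate Hi-C pairs onto reconstructed sequences,
    dropping ends that fall outside any placed interval (unmapped reads)."""
    rows = []
    for r in pairs.itertuples():
        a = lift_position(trees, r.chrom1, int(r.pos1))
        b = lift_position(trees, r.chrom2, int(r.pos2))
        if a is None or b is None:
            continue
        rows.append((a[0], a[1], int(r.mapq1), b[0], b[1], int(r.mapq2)))
    return pd.DataFrame(
        rows, columns=["seq1", "pos1", "mapq1", "seq2", "pos2", "mapq2"]
    )


# ---------------------------------------------------------------------------
# depth track (uniform shotgun coverage with sampling noise)


def simulate_depth_bed(
    seq_lengths: dict[str, int],
    mean_depth: float = 14.0,
    window: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window read depth as a 3+1 column BED-like frame
    (seq, start, end, depth)."""
    rng = np.random.default_rng([seed % (2**31), 7])
    rows = []
    for seq, ln in seq_lengths.items():
        starts = np.arange(0, ln, window)
        depths = rng.poisson(mean_depth, starts.size)
        for s, d in zip(starts, depths):
            rows.append((seq, int(s), int(min(s + window, ln)), int(d)))
    return pd.DataFrame(rows, columns=["seq", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# FASTA helpers


def library_fasta(library: dict[str, BacAssembly]) -> dict[str, str]:
    """All scaffold sequences keyed by '<bac>.s<j>' record names."""
    out: dict[str, str] = {}
    for assembly in library.values():
        out.update(assembly.sequences())
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
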