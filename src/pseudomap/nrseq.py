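"""Non-redundant (NR) sequence construction per BAC cluster.

Each cluster's scaffolds are merged into a non-redundant representation by
an iterative visited/unvisited scheme: the largest scaffold seeds the
visited set; remaining scaffolds are aligned to the visited set (>= 500 bp,
>= 99.5% identity, alignments only between BACs at most 10 apart in the
cluster MST), aligned regions are subtracted from the unvisited copies,
remnants with fewer than 500 proper nucleotides are discarded, and the
largest remaining scaffold is promoted — until nothing is left unvisited.
Terminal N runs of the resulting fragments are trimmed.

Every NR base is traceable to its source (BAC, scaffold, interval) through
the provenance table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .align import align_pairwise
from .graph import Backbone
from .intervals import subtract_intervals
from .overlaps import bac_of

MIN_ALIGN_LENGTH = 500
MIN_ALIGN_IDENTITY = 99.5
MIN_PROPER_NT = 500
MAX_MST_HOPS = 10

_ACGT = re.compile("[ACGTacgt]")


def _proper_nt(seq: str) -> int:
    return len(_ACGT.findall(seq))


@dataclass
class _ScafState:
    bac: str
    scaffold: str
    seq: str
    kept: list[tuple[int, int]]

    def remaining(self) -> int:
        return sum(_proper_nt(self.seq[a:b]) for a, b in self.kept)

    def fragments(self) -> dict[str, str]:
        return {
            f"{self.scaffold}@{a}-{b}": self.seq[a:b] for a, b in self.kept
        }


def _hop_distances(backbone: Backbone) -> dict[str, dict[str, int]]:
    return {
        u: dict(d)
        for u, d in nx.all_pairs_shortest_path_length(backbone.mst)
    }


def build_nr(
    cluster_id: str,
    members: list[str],
    scaffolds: dict[str, dict[str, str]],
    backbone: Backbone | None,
    max_hops: int = MAX_MST_HOPS,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Non-redundant sequence of one cluster.

    ``scaffolds`` maps each member BAC to its scaffold sequences. Returns
    (NR records, provenance) where provenance columns are
    (seq, start, end, bac, scaffold, scf_start, scf_end, strand); each NR
    record is one scaffold-oriented fragment, so start is 0 and strand +1.
    """
    if not members:
        raise ValueError(f"empty cluster {cluster_id!r}")
    hops = _hop_distances(backbone) if backbone is not None else None
    states = [
        _ScafState(b, sid, seq, [(0, len(seq))])
        for b in sorted(members)
        for sid, seq in sorted(scaffolds[b].items())
    ]
    unvisited = {s.scaffold: s for s in states}
    visited_order: list[tuple[_ScafState, list[tuple[int, int]]]] = []
    while unvisited:
        # promote the largest remaining scaffold (ties break lexicographically)
        nxt = max(
            unvisited.values(), key=lambda s: (s.remaining(), _revlex(s.scaffold))
        )
        promoted = unvisited.pop(nxt.scaffold)
        frozen = [iv for iv in promoted.kept]
        visited_order.append((promoted, frozen))
        if not unvisited:
            break
        subjects = {
            name: seq
            for name, seq in promoted.fragments().items()
            if len(seq) >= MIN_ALIGN_LENGTH
        }
        if not subjects:
            continue
        queries = {}
        qmap = {}
        for s in unvisited.values():
            if hops is not None:
                d = hops.get(promoted.bac, {}).get(s.bac)
                if d is None or d > max_hops:
                    continue
            for name, seq in s.fragments().items():
                if len(seq) >= MIN_ALIGN_LENGTH:
                    queries[name] = seq
                    qmap[name] = s
        if not queries:
            continue
        hsps = align_pairwise(
            queries, subjects,
            min_identity=MIN_ALIGN_IDENTITY, min_length=MIN_ALIGN_LENGTH,
            skip_self=False,
        )
        cut: dict[str, list[tuple[int, int]]] = {}
        for h in hsps:
            cut.setdefault(h.query, []).append(h.query_interval())
        for qname, ivs in cut.items():
            s = qmap[qname]
            base = int(qname.rsplit("@", 1)[1].split("-")[0])
            shifted = [(base + a, base + b) for a, b in ivs]
            s.kept = subtract_intervals(s.kept, shifted)
        # discard scaffolds reduced below the proper-nucleotide floor
        for sid in list(unvisited):
            if unvisited[sid].remaining() < MIN_PROPER_NT:
                del unvisited[sid]
    # emit fragments, trimming terminal N runs
    nr: dict[str, str] = {}
    prov_rows = []
    n = 0
    for state, kept in visited_order:
        for a, b in kept:
            frag = state.seq[a:b]
            lead = len(frag) - len(frag.lstrip("Nn"))
            trail = len(frag) - len(frag.rstrip("Nn"))
            a2, b2 = a + lead, b - trail
            frag = state.seq[a2:b2]
            if _proper_nt(frag) < MIN_PROPER_NT:
                continue
            n += 1
            name = f"{cluster_id}_f{n:04d}"
            nr[name] = frag
            prov_rows.append(
                (name, 0, len(frag), state.bac, state.scaffold, a2, b2, 1)
            )
    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "seq", "start", "end", "bac", "scaffold", "scf_start", "scf_end",
            "strand",
        ],
    )
    return nr, provenance


def _revlex(s: str):
    """Key that sorts lexicographically *smaller* strings higher, so that
    max() with (remaining, key) prefers the smaller scaffold id on ties."""
    return tuple(-ord(c) for c in s)


def self_redundancy_hits(
    nr: dict[str, str],
    provenance: pd.DataFrame,
    backbone: Backbone | None,
    max_hops: int = MAX_MST_HOPS,
):
    """Residual-redundancy check: HSPs >= 500 bp / >= 99.5% identity between
    NR fragments whose source BACs are within ``max_hops`` in the MST.
    An empty result certifies the NR construction."""
    hsps = align_pairwise(
        nr, nr, min_identity=MIN_ALIGN_IDENTITY, min_length=MIN_ALIGN_LENGTH,
        skip_self=True,
    )
    src = dict(zip(provenance["seq"], provenance["bac"]))
    hops = _hop_distances(backbone) if backbone is not None else None
    out = []
    for h in hsps:
        if h.query == h.subject:
            continue
        ba, bb = src[h.query], src[h.subject]
        if hops is not None and ba != bb:
            d = hops.get(ba, {}).get(bb)
            if d is None or d > max_hops:
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# gene-bearing sequence rescue


def rescue_gene_sequences(
    gene_hits_nr: pd.DataFrame,
    gene_hits_all_bacs: pd.DataFrame,
    gene_hits_wgs: pd.DataFrame,
    nr: dict[str, str],
    provenance: pd.DataFrame,
    cluster_of_bac: dict[str, str],
    bac_scaffolds: dict[str, str],
    wgs_seqs: dict[str, str],
    min_gain: float = 0.05,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Recover genes under-represented in the NR sequence.

    Hit tables have columns (gene, target, cds_fraction): the fraction of a
    gene's coding sequence covered by its best spliced alignment to the
    target. Two amendments are made:

    (a) swap-in: a gene whose best hit among all clustered BAC scaffolds
    covers at least 5 percentage points more CDS than its best NR hit gets
    that scaffold aligned to its cluster's NR; covered old NR regions are
    removed and the scaffold is inserted instead;

    (b) genes absent from the NR but present on WGS contigs (or excluded
    BAC scaffolds passed in ``bac_scaffolds``) contribute their carrier's
    NR-unmatched remnants (>= 500 bp) to the chrUn pool.

    Returns (updated NR, updated provenance, chrUn additions).
    """
    for name, df in (
        ("gene_hits_nr", gene_hits_nr),
        ("gene_hits_all_bacs", gene_hits_all_bacs),
        ("gene_hits_wgs", gene_hits_wgs),
    ):
        if not df.empty and (
            (df["cds_fraction"] < 0).any() or (df["cds_fraction"] > 1).any()
        ):
            raise ValueError(f"{name}: cds_fraction outside [0, 1]")
    nr = dict(nr)
    prov = provenance.copy()
    chrun: dict[str, str] = {}

    best_nr = (
        gene_hits_nr.groupby("gene")["cds_fraction"].max()
        if not gene_hits_nr.empty
        else pd.Series(dtype=float)
    )
    # (a) swap better BAC scaffolds into the NR
    if not gene_hits_all_bacs.empty:
        idx = gene_hits_all_bacs.groupby("gene")["cds_fraction"].idxmax()
        for r in gene_hits_all_bacs.loc[idx].itertuples():
            gene, target = str(r.gene), str(r.target)
            nr_frac = float(best_nr.get(gene, 0.0))
            if float(r.cds_fraction) < nr_frac + min_gain:
                continue
            bac = bac_of(target)
            cluster = cluster_of_bac.get(bac)
            if cluster is None or target not in bac_scaffolds:
                continue
            seq = bac_scaffolds[target]
            cluster_records = {
                name: s for name, s in nr.items() if name.startswith(cluster + "_")
            }
            nr, prov = _replace_covered(
                nr, prov, cluster_records, target, seq, bac, cluster
            )
    # (b) genes only on WGS contigs or excluded BACs: keep NR-unmatched parts
    represented = set(best_nr.index)
    for df, seqs in ((gene_hits_wgs, wgs_seqs), ):
        if df.empty:
            continue
        for r in df.itertuples():
            gene, target = str(r.gene), str(r.target)
            if gene in represented or target not in seqs:
                continue
            remnants = _nr_unmatched(seqs[target], nr)
            for i, (a, b) in enumerate(remnants):
                if b - a >= 500:
                    chrun[f"chrUn_{target}_{i}"] = seqs[target][a:b]
            represented.add(gene)
    return nr, prov, chrun


def _replace_covered(nr, prov, cluster_records, target, seq, bac, cluster):
    """Remove NR regions covered by ``seq`` and insert it as a new record."""
    hsps = align_pairwise(
        {target: seq}, cluster_records,
        min_identity=MIN_ALIGN_IDENTITY, min_length=MIN_ALIGN_LENGTH,
        skip_self=False,
    )
    covered: dict[str, list[tuple[int, int]]] = {}
    for h in hsps:
        covered.setdefault(h.subject, []).append(h.subject_interval())
    new_rows = []
    for r in prov.itertuples():
        if r.seq not in covered:
            new_rows.append(
                (r.seq, r.start, r.end, r.bac, r.scaffold, r.scf_start,
                 r.scf_end, r.strand)
            )
            continue
        old = nr.pop(r.seq)
        kept = subtract_intervals([(0, len(old))], covered[r.seq])
        for a, b in kept:
            if _proper_nt(old[a:b]) < MIN_PROPER_NT:
                continue
            name = f"{r.seq}:{a}-{b}"
            nr[name] = old[a:b]
            new_rows.append(
                (name, 0, b - a, r.bac, r.scaffold, r.scf_start + a,
                 r.scf_start + b, r.strand)
            )
    new_name = f"{cluster}_swap_{target}"
    nr[new_name] = seq
    new_rows.append((new_name, 0, len(seq), bac, target, 0, len(seq), 1))
    prov = pd.DataFrame(new_rows, columns=list(prov.columns))
    return nr, prov


def _nr_unmatched(seq: str, nr: dict[str, str]) -> list[tuple[int, int]]:
    hsps = align_pairwise(
        {"carrier": seq}, nr,
        min_identity=MIN_ALIGN_IDENTITY, min_length=MIN_ALIGN_LENGTH,
        skip_self=False,
    )
    covered = [h.query_interval() for h in hsps]
    return subtract_intervals([(0, len(seq))], covered)
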