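"""The BAC overlap graph: evidence-weighted clustering with a branch-free,
map-consistent invariant.

Nodes are BAC assemblies; edges carry the cumulative overlap length (bp) and
an evidence tag. Connected components ("clusters") are the sequence-based
analogue of physical contigs. Each cluster is summarised by a minimum
spanning tree whose longest geodesic (the *diameter*) serves as the linear
backbone; the hop distance of a node to the backbone is its *rank*, nodes
attached to the same backbone node form a *BAC bin*, and any node of rank
greater than one constitutes a *branch* — which cannot occur in a linear
genome and therefore marks a spurious alignment or a chimeric assembly.

The graph is built in twelve steps. Step 1 links BACs within physical-map
(FP) contigs from permissive sequence overlaps; step 2 adds stringent
overlap links across FP contigs; steps 3-12 add joins supported by
combinations of optical-map (OM) alignments, BAC-end sequences (BES),
physical-map adjacency, "link BACs" and singleton bridges. After every
step the branch-free and map-consistency invariants are restored, either by
the prescribed pruning sequence (steps 1-2) or by rolling back offending
candidate edges (steps 3-12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .anchor import (
    ANCHORED,
    INCONSISTENT,
    UNANCHORED,
    BacAnchor,
    ClusterAnchor,
    anchor_cluster,
)
from .overlaps import OverlapCall
from .simulate import BAND_KB, BacAssembly

log = logging.getLogger(__name__)

MAX_BAC_LENGTH = 300_000  # assemblies longer than this are excluded outright


# ---------------------------------------------------------------------------
# backbone


@dataclass
class Backbone:
    """MST summary of one cluster: diameter path, ranks and BAC bins."""

    mst: nx.Graph
    diameter: list[str]
    rank: dict[str, int]
    attachment: dict[str, str]

    @property
    def branched(self) -> bool:
        return any(r > 1 for r in self.rank.values())

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, att in self.attachment.items():
            out.setdefault(att, []).append(node)
        return {k: sorted(v) for k, v in out.items()}

    def branch_nodes(self) -> list[str]:
        """Off-backbone nodes of bins that contain a rank>1 node."""
        bad_bins = {self.attachment[n] for n, r in self.rank.items() if r > 1}
        return sorted(
            n
            for n, r in self.rank.items()
            if r >= 1 and self.attachment[n] in bad_bins
        )

    def hop_distance(self, a: str, b: str) -> int:
        return nx.shortest_path_length(self.mst, a, b)


def compute_backbone(sub: nx.Graph, negate_weights: bool = True) -> Backbone:
    """MST (Prim), diameter, ranks and bins of a connected subgraph.

    The MST is computed on negated overlap lengths by default, so the tree
    retains the strongest overlaps. Diameter ties break to the
    lexicographically smallest terminal pair; the path is listed from its
    smaller terminal.
    """
    if sub.number_of_nodes() == 0:
        raise ValueError("empty cluster")
    if not nx.is_connected(sub):
        raise ValueError("disconnected input; pass one cluster at a time")
    work = nx.Graph()
    work.add_nodes_from(sub.nodes)
    for u, v, d in sub.edges(data=True):
        w = float(d.get("weight", 0.0))
        work.add_edge(u, v, _mstw=-w if negate_weights else w)
    mst = nx.minimum_spanning_tree(work, weight="_mstw", algorithm="prim")
    # unweighted diameter with deterministic tie-break
    best_pair: tuple[str, str] | None = None
    best_len = -1
    for u in sorted(mst.nodes):
        dist = nx.single_source_shortest_path_length(mst, u)
        far = max(dist.values())
        if far < best_len:
            continue
        for v, dv in sorted(dist.items()):
            if dv != far:
                continue
            pair = tuple(sorted((u, v)))
            if far > best_len or (best_pair is not None and pair < best_pair):
                best_len, best_pair = far, pair
    a, b = best_pair  # type: ignore[misc]
    diameter = nx.shortest_path(mst, a, b)
    on_path = set(diameter)
    rank = {n: 0 for n in on_path}
    attachment = {n: n for n in on_path}
    frontier = list(diameter)
    while frontier:
        nxt = []
        for u in frontier:
            for v in mst.neighbors(u):
                if v in rank:
                    continue
                rank[v] = rank[u] + 1
                attachment[v] = attachment[u]
                nxt.append(v)
        frontier = nxt
    return Backbone(mst, diameter, rank, attachment)


# ---------------------------------------------------------------------------
# graph state


@dataclass
class BacMeta:
    bac: str
    length: int
    n50: int
    is_mtp: bool
    gene_bearing: bool
    fp_contig: str | None
    fp_band: float | None


def meta_from_library(library: dict[str, BacAssembly]) -> dict[str, BacMeta]:
    return {
        b: BacMeta(
            b, a.length, a.n50, a.is_mtp, a.gene_bearing, a.fp_contig, a.fp_band
        )
        for b, a in library.items()
    }


class OverlapGraph:
    """Mutable overlap-graph state with cached backbones."""

    def __init__(self, meta: dict[str, BacMeta], anchors: dict[str, BacAnchor]):
        self.g = nx.Graph()
        self.meta = meta
        self.anchors = anchors
        self.excluded: dict[str, str] = {}
        self._bb_cache: dict[frozenset, Backbone] = {}

    # -- structure queries ---------------------------------------------------

    def components(self) -> list[frozenset]:
        return sorted(
            (frozenset(c) for c in nx.connected_components(self.g)),
            key=lambda c: min(c),
        )

    def clusters(self) -> list[frozenset]:
        return [c for c in self.components() if len(c) > 1]

    def singletons(self) -> list[str]:
        return sorted(n for n in self.g.nodes if self.g.degree[n] == 0)

    def component_of(self, node: str) -> frozenset:
        return frozenset(nx.node_connected_component(self.g, node))

    def backbone(self, comp: frozenset) -> Backbone:
        if comp not in self._bb_cache:
            self._bb_cache[comp] = compute_backbone(self.g.subgraph(comp))
        return self._bb_cache[comp]

    def cluster_anchor(self, comp: frozenset) -> ClusterAnchor:
        return anchor_cluster([self.anchors[b] for b in comp])

    def ends(self, comp: frozenset, termini_only: bool = False) -> set[str]:
        """Cluster ends: the two diameter termini plus their rank-1
        attachments (configurable to termini only)."""
        if len(comp) == 1:
            return set(comp)
        bb = self.backbone(comp)
        termini = {bb.diameter[0], bb.diameter[-1]}
        if termini_only:
            return termini
        extra = {
            n
            for n, r in bb.rank.items()
            if r == 1 and bb.attachment[n] in termini
        }
        return termini | extra

    # -- mutation ------------------------------------------------------------

    def _invalidate(self) -> None:
        self._bb_cache.clear()

    def add_node(self, bac: str) -> None:
        self.g.add_node(bac)
        self._invalidate()

    def add_edge(self, u: str, v: str, weight: float, evidence: str, step: int):
        self.g.add_edge(u, v, weight=float(weight), evidence=evidence, step=step)
        self._invalidate()

    def remove_edge(self, u: str, v: str) -> None:
        self.g.remove_edge(u, v)
        self._invalidate()

    def remove_node(self, bac: str, reason: str) -> None:
        if self.g.has_node(bac):
            self.g.remove_node(bac)
        self.excluded[bac] = reason
        self._invalidate()

    # -- invariants ----------------------------------------------------------

    def branched_clusters(self) -> list[frozenset]:
        return [c for c in self.clusters() if self.backbone(c).branched]

    def inconsistent_clusters(self) -> list[frozenset]:
        return [
            c
            for c in self.clusters()
            if self.cluster_anchor(c).status == INCONSISTENT
        ]

    def assert_invariants(self) -> None:
        assert not self.branched_clusters(), "branched cluster remains"
        assert not self.inconsistent_clusters(), "map-inconsistent cluster remains"

    # -- statistics ----------------------------------------------------------

    def stats(self, step: int) -> dict:
        sizes = sorted((len(c) for c in self.clusters()), reverse=True)
        in_clusters = sum(sizes)
        n50 = 0
        acc = 0
        for s in sizes:
            acc += s
            if acc * 2 >= in_clusters:
                n50 = s
                break
        return {
            "step": step,
            "clusters": len(sizes),
            "bacs_in_clusters": in_clusters,
            "singletons": len(self.singletons()),
            "excluded": len(self.excluded),
            "cluster_n50": n50,
            "mean_cluster_size": in_clusters / len(sizes) if sizes else 0.0,
            "bac_weighted_mean_size": (
                sum(s * s for s in sizes) / in_clusters if in_clusters else 0.0
            ),
        }

    def cluster_map(self) -> dict[str, list[str]]:
        """Stable cluster ids ('cl_0001', ...) ordered by smallest member."""
        return {
            f"cl_{i + 1:04d}": sorted(c)
            for i, c in enumerate(self.components())
        }

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (min(u, v), max(u, v), d["weight"], d["evidence"], d["step"])
            for u, v, d in self.g.edges(data=True)
        ]
        return pd.DataFrame(
            sorted(rows), columns=["bac_a", "bac_b", "weight", "evidence", "step"]
        )

    def write_graphml(self, path) -> None:
        """Export the graph with node metadata and edge evidence tags."""
        g = nx.Graph()
        for n in self.g.nodes:
            m = self.meta[n]
            g.add_node(
                n, length=m.length, n50=m.n50, is_mtp=m.is_mtp,
                gene_bearing=m.gene_bearing, fp_contig=m.fp_contig or "",
            )
        for u, v, d in self.g.edges(data=True):
            g.add_edge(u, v, weight=d["weight"], evidence=d["evidence"],
                       step=d["step"])
        nx.write_graphml(g, str(path))


def cm_distance(a: BacAnchor, b: BacAnchor) -> float:
    """Absolute cM distance within one chromosome; inf across chromosomes
    or when either anchor is missing."""
    if a.status != ANCHORED or b.status != ANCHORED or a.chrom != b.chrom:
        return float("inf")
    return abs(a.cm - b.cm)


# ---------------------------------------------------------------------------
# evidence bundle used by steps 2-12


@dataclass
class RefinementEvidence:
    calls: dict[tuple[str, str], OverlapCall] = field(default_factory=dict)
    om: pd.DataFrame | None = None
    bes: pd.DataFrame | None = None
    wgs_hits: pd.DataFrame | None = None  # wgs_contig, bac, chrom, cm

    @classmethod
    def build(cls, overlap_calls, om=None, bes=None, wgs_hits=None, wgs_map=None):
        calls = {(c.bac_a, c.bac_b): c for c in overlap_calls}
        hits = None
        if wgs_hits is not None and wgs_map is not None:
            hits = wgs_hits.merge(wgs_map, on="wgs_contig", how="inner")
        return cls(calls, om, bes, hits)

    def call(self, a: str, b: str) -> OverlapCall | None:
        return self.calls.get((min(a, b), max(a, b)))


def _extent_fraction_ok(call: OverlapCall, la: int, lb: int, frac: float) -> bool:
    """Overlap accounts for >= frac of the length of either BAC."""
    ext_a = call.extent_on(call.bac_a)
    ext_b = call.extent_on(call.bac_b)
    return ext_a >= frac * la or ext_b >= frac * lb


def _edge_weight(call: OverlapCall) -> float:
    return float(max(call.extent_a, call.extent_b))


# ---------------------------------------------------------------------------
# step 1


def build_initial_graph(
    meta: dict[str, BacMeta],
    overlap_calls,
    anchors: dict[str, BacAnchor],
) -> OverlapGraph:
    """Initial overlap graph from permissive overlaps within FP contigs.

    Inconsistently anchored clones and clones longer than 300 kb are
    excluded. An edge requires the same FP contig, a permissive overlap
    extent of at least 5% of either clone's length, and genetic agreement
    (same chromosome within 3 cM) unless a party is unanchored. The raw
    graph is then made branch-free and map-consistent.
    """
    og = OverlapGraph(meta, anchors)
    for b, m in meta.items():
        if anchors[b].status == INCONSISTENT:
            og.excluded[b] = "inconsistent_anchor"
        elif m.length > MAX_BAC_LENGTH:
            og.excluded[b] = "overlong_assembly"
        else:
            og.g.add_node(b)
    for call in overlap_calls:
        a, b = call.bac_a, call.bac_b
        if a in og.excluded or b in og.excluded:
            continue
        if a not in meta or b not in meta:
            continue
        ma, mb = meta[a], meta[b]
        if ma.fp_contig is None or ma.fp_contig != mb.fp_contig:
            continue
        if not _extent_fraction_ok(call, ma.length, mb.length, 0.05):
            continue
        aa, ab = anchors[a], anchors[b]
        both = aa.status == ANCHORED and ab.status == ANCHORED
        if both and cm_distance(aa, ab) > 3.0:
            continue
        og.add_edge(a, b, _edge_weight(call), "overlap", 1)
    # resolution, in order: unanchored edges in inconsistent clusters,
    # non-MTP branch nodes (twice), gene-bearing branch nodes, the rest
    _drop_unanchored_edges_in_inconsistent(og)
    for _ in range(2):
        _remove_branch_nodes(og, lambda m: not m.is_mtp, "branch_nonmtp")
    _remove_branch_nodes(og, lambda m: m.gene_bearing, "branch_genebearing")
    _remove_branch_nodes(og, lambda m: True, "branch_residual", repeat=True)
    _enforce_map_consistency(og)
    return og


def _drop_unanchored_edges_in_inconsistent(og: OverlapGraph) -> None:
    changed = True
    while changed:
        changed = False
        for comp in og.inconsistent_clusters():
            for u, v in list(og.g.subgraph(comp).edges):
                if (
                    og.anchors[u].status != ANCHORED
                    or og.anchors[v].status != ANCHORED
                ):
                    og.remove_edge(u, v)
                    changed = True


def _remove_branch_nodes(og: OverlapGraph, predicate, reason: str,
                         repeat: bool = False) -> None:
    while True:
        victims = []
        for comp in og.branched_clusters():
            bb = og.backbone(comp)
            victims.extend(
                n for n in bb.branch_nodes() if predicate(og.meta[n])
            )
        if not victims:
            return
        for n in sorted(set(victims)):
            og.remove_node(n, reason)
        if not repeat:
            return


def _enforce_map_consistency(og: OverlapGraph) -> None:
    """Safeguard: restore map consistency if the prescribed edge removals
    left an inconsistent cluster (remove the farthest-outlier member)."""
    _drop_unanchored_edges_in_inconsistent(og)
    guard = 0
    while True:
        bad = og.inconsistent_clusters()
        if not bad or guard > 500:
            break
        guard += 1
        comp = bad[0]
        anchored = [b for b in comp if og.anchors[b].status == ANCHORED]
        chroms = pd.Series([og.anchors[b].chrom for b in anchored])
        modal = chroms.mode().iloc[0]
        off = [b for b in anchored if og.anchors[b].chrom != modal]
        if off:
            victim = sorted(off)[0]
        else:
            med = float(np.median([og.anchors[b].cm for b in anchored]))
            victim = max(
                sorted(anchored), key=lambda b: abs(og.anchors[b].cm - med)
            )
        og.remove_node(victim, "map_outlier")


# ---------------------------------------------------------------------------
# step 2


def step2_add_links(og: OverlapGraph, ev: RefinementEvidence) -> None:
    """Stringent overlap links across FP contigs, followed by the full
    branch-pruning sequence."""
    for (a, b), call in sorted(ev.calls.items()):
        if call.klass != "stringent":
            continue
        if not (og.g.has_node(a) and og.g.has_node(b)):
            continue
        if og.g.has_edge(a, b):
            continue
        ma, mb = og.meta[a], og.meta[b]
        if not _extent_fraction_ok(call, ma.length, mb.length, 0.10):
            continue
        if cm_distance(og.anchors[a], og.anchors[b]) > 3.0:
            continue
        og.add_edge(a, b, _edge_weight(call), "overlap", 2)
    # pruning order: short/fragmented first, then non-MTP (x2), cross-FPC
    # branch edges, non-MTP again, overlong, gene-bearing, the rest
    _remove_branch_nodes(
        og, lambda m: m.length < 50_000 or m.n50 < 10_000, "branch_short"
    )
    for _ in range(2):
        _remove_branch_nodes(og, lambda m: not m.is_mtp, "branch_nonmtp")
    _drop_cross_fpc_branch_edges(og)
    _remove_branch_nodes(og, lambda m: not m.is_mtp, "branch_nonmtp")
    _remove_branch_nodes(og, lambda m: m.length > 250_000, "branch_overlong")
    _remove_branch_nodes(og, lambda m: m.gene_bearing, "branch_genebearing")
    _remove_branch_nodes(og, lambda m: True, "branch_residual", repeat=True)
    _enforce_map_consistency(og)


def _drop_cross_fpc_branch_edges(og: OverlapGraph) -> None:
    victims = []
    for comp in og.branched_clusters():
        bb = og.backbone(comp)
        branch = set(bb.branch_nodes())
        for u, v in og.g.subgraph(comp).edges:
            if (
                u in branch
                and v in branch
                and og.meta[u].fp_contig != og.meta[v].fp_contig
            ):
                victims.append((u, v))
    for u, v in victims:
        if og.g.has_edge(u, v):
            og.remove_edge(u, v)


# ---------------------------------------------------------------------------
# optical-map join support


def om_best_alignments(om: pd.DataFrame) -> pd.DataFrame:
    """Retain only the best (highest-confidence) alignment per BAC
    sequence contig."""
    return (
        om.sort_values(["bac", "scaffold", "confidence"])
        .groupby(["bac", "scaffold"], as_index=False)
        .tail(1)
    )


def om_join_support(
    og: OverlapGraph,
    comp_a: frozenset,
    comp_b: frozenset,
    om_best: pd.DataFrame,
    min_confidence: float = 25.0,
    max_gap: int = 300_000,
    min_rank_corr: float = 0.5,
) -> tuple[bool, str | None]:
    """Do the two clusters share an optical-map contig that joins them?

    A cluster is OM-aligned if the confidence of its contigs' best
    alignments to one OM contig sums to at least 25. Two clusters are
    joined when their alignment footprints on a shared OM contig are at
    most 300 kb apart (overlapping footprints count as distance 0) and, for
    both clusters, the rank correlation between backbone order and OM
    positions exceeds 0.5.
    """

    def profile(comp):
        sub = om_best[om_best["bac"].isin(comp)]
        out = {}
        for om_id, grp in sub.groupby("om_contig"):
            if grp["confidence"].sum() < min_confidence:
                continue
            per_bac = grp.groupby("bac")["om_pos"].median()
            out[om_id] = (
                float(grp["om_pos"].min()),
                float(grp["om_pos"].max()),
                per_bac,
            )
        return out

    pa, pb = profile(comp_a), profile(comp_b)
    for om_id in sorted(set(pa) & set(pb)):
        lo_a, hi_a, pos_a = pa[om_id]
        lo_b, hi_b, pos_b = pb[om_id]
        gap = max(0.0, max(lo_a, lo_b) - min(hi_a, hi_b))
        if gap > max_gap:
            continue
        if _backbone_om_corr(og, comp_a, pos_a) <= min_rank_corr:
            continue
        if _backbone_om_corr(og, comp_b, pos_b) <= min_rank_corr:
            continue
        return True, om_id
    return False, None


def _backbone_om_corr(og: OverlapGraph, comp: frozenset, om_pos: pd.Series) -> float:
    """Spearman correlation between diameter order and OM positions;
    clusters too small to measure pass (correlation 1)."""
    if len(comp) == 1:
        return 1.0
    diameter = og.backbone(comp).diameter
    points = [(i, om_pos[b]) for i, b in enumerate(diameter) if b in om_pos.index]
    if len(points) < 2:
        return 1.0
    if len(points) == 2:
        return 1.0 if points[1][1] >= points[0][1] else -1.0
    rho = spearmanr([p[0] for p in points], [p[1] for p in points]).statistic
    return float(rho) if np.isfinite(rho) else 1.0


# ---------------------------------------------------------------------------
# candidate machinery for steps 3-12


@dataclass(frozen=True)
class Candidate:
    edges: tuple[tuple[str, str], ...]
    weight: float  # supporting-evidence strength; higher commits first
    evidence: str
    new_nodes: tuple[str, ...] = ()

    def sort_key(self):
        return (-self.weight, tuple(sorted(self.edges)))


def add_edges_with_rollback(
    og: OverlapGraph, candidates: list[Candidate], step: int
) -> list[Candidate]:
    """Commit candidates in deterministic order (evidence strength
    descending, then lexicographic pair ids), rolling back any candidate
    whose inclusion branches a cluster or breaks map consistency."""
    committed = []
    for cand in sorted(candidates, key=Candidate.sort_key):
        prior_reason = {n: og.excluded.get(n) for n in cand.new_nodes}
        for n in cand.new_nodes:
            if n in og.excluded:
                del og.excluded[n]
            og.add_node(n)

        def _roll_back_nodes():
            for n in cand.new_nodes:
                og.remove_node(n, prior_reason[n] or "rolled_back")

        # skip joins that became internal after earlier commits
        if not cand.new_nodes and all(
            og.g.has_node(u)
            and og.g.has_node(v)
            and nx.has_path(og.g, u, v)
            for u, v in cand.edges
        ):
            continue
        added = []
        ok = True
        for u, v in cand.edges:
            if not (og.g.has_node(u) and og.g.has_node(v)):
                ok = False
                break
            if not og.g.has_edge(u, v):
                og.add_edge(u, v, 0.0, cand.evidence, step)
                added.append((u, v))
        if ok and added:
            comp = og.component_of(added[0][0])
            if len(comp) > 1 and (
                og.backbone(comp).branched
                or og.cluster_anchor(comp).status == INCONSISTENT
            ):
                ok = False
        if not ok or not added:
            for u, v in added:
                og.remove_edge(u, v)
            _roll_back_nodes()
            continue
        committed.append(cand)
    return committed


# ---------------------------------------------------------------------------
# steps 3-12 proposal logic


def propose_joins(
    og: OverlapGraph, step: int, ev: RefinementEvidence
) -> list[Candidate]:
    """Candidate edges for one refinement step (3-12)."""
    proposers = {
        3: _propose_step3,
        4: lambda og, ev: _propose_bes(og, ev, require_fpc=True, require_om=True),
        5: lambda og, ev: _propose_bes(og, ev, require_fpc=True, require_om=False),
        6: _propose_step6,
        7: _propose_step7,
        8: _propose_step8,
        9: _propose_step9,
        10: _propose_step10,
        11: _propose_step11,
        12: lambda og, ev: _propose_bes(og, ev, require_fpc=False, require_om=True),
    }
    if step not in proposers:
        raise ValueError(f"unknown refinement step: {step}")
    return proposers[step](og, ev)


def _cluster_index(og: OverlapGraph):
    comps = og.components()
    which = {n: i for i, c in enumerate(comps) for n in c}
    return comps, which


def _om_joined_pairs(og: OverlapGraph, ev: RefinementEvidence):
    """All cluster pairs supported by a shared OM contig."""
    if ev.om is None or ev.om.empty:
        return []
    best = om_best_alignments(ev.om)
    comps, _ = _cluster_index(og)
    out = []
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            ok, om_id = om_join_support(og, comps[i], comps[j], best)
            if ok:
                out.append((comps[i], comps[j], om_id))
    return out


def _propose_step3(og, ev):
    """Permissive overlaps (>=10% of either clone) between cluster ends,
    within 3 cM, requiring OM support for the two clusters."""
    candidates = []
    for comp_a, comp_b, _ in _om_joined_pairs(og, ev):
        ends_a, ends_b = og.ends(comp_a), og.ends(comp_b)
        for a in sorted(ends_a):
            for b in sorted(ends_b):
                call = ev.call(a, b)
                if call is None or call.klass == "none":
                    continue
                if not _extent_fraction_ok(
                    call, og.meta[a].length, og.meta[b].length, 0.10
                ):
                    continue
                if cm_distance(og.anchors[a], og.anchors[b]) > 3.0:
                    continue
                candidates.append(
                    Candidate(((a, b),), _edge_weight(call), "OM")
                )
    return candidates


def _propose_bes(og, ev, require_fpc: bool, require_om: bool):
    """BES-pair joins: the two mates of one BAC-end pair hit end BACs of
    two different clusters."""
    if ev.bes is None or ev.bes.empty:
        return []
    comps, which = _cluster_index(og)
    end_sets = [og.ends(c) for c in comps]
    om_ok = None
    if require_om:
        om_ok = {
            (min(min(a), min(b)), max(min(a), min(b)))
            for a, b, _ in _om_joined_pairs(og, ev)
        }
    candidates = []
    for _, grp in ev.bes.groupby("bes_pair"):
        left = sorted(set(grp.loc[grp["mate"] == "L", "bac"]))
        right = sorted(set(grp.loc[grp["mate"] == "R", "bac"]))
        for b1 in left:
            for b2 in right:
                if b1 == b2:
                    continue
                if not (og.g.has_node(b1) and og.g.has_node(b2)):
                    continue
                i, j = which[b1], which[b2]
                if i == j:
                    continue
                if b1 not in end_sets[i] or b2 not in end_sets[j]:
                    continue
                m1, m2 = og.meta[b1], og.meta[b2]
                weight = 0.0
                if require_fpc:
                    if m1.fp_contig is None or m1.fp_contig != m2.fp_contig:
                        continue
                    band_gap = abs((m1.fp_band or 0) - (m2.fp_band or 0))
                    if band_gap * BAND_KB * 1000 >= 200_000:
                        continue
                    weight = -band_gap
                if require_om:
                    key = (
                        min(min(comps[i]), min(comps[j])),
                        max(min(comps[i]), min(comps[j])),
                    )
                    if key not in om_ok:
                        continue
                candidates.append(Candidate(((b1, b2),), weight, "BES"))
    return candidates


def _propose_step6(og, ev):
    """Link BACs: inconsistently anchored clones whose stringent overlaps
    to two cluster-end BACs bridge their clusters; the link BAC itself is
    not added."""
    comps, which = _cluster_index(og)
    end_sets = [og.ends(c) for c in comps]
    link_bacs = sorted(
        b for b, r in og.excluded.items() if r == "inconsistent_anchor"
    )
    partners: dict[str, list[tuple[str, float]]] = {}
    for link in link_bacs:
        for (a, b), call in ev.calls.items():
            if call.klass != "stringent" or link not in (a, b):
                continue
            other = b if a == link else a
            if not og.g.has_node(other):
                continue
            if not _extent_fraction_ok(
                call, og.meta[call.bac_a].length, og.meta[call.bac_b].length, 0.10
            ):
                continue
            partners.setdefault(link, []).append((other, _edge_weight(call)))
    candidates = []
    for link, plist in sorted(partners.items()):
        for x in range(len(plist)):
            for y in range(x + 1, len(plist)):
                (b1, w1), (b2, w2) = plist[x], plist[y]
                i, j = which[b1], which[b2]
                if i == j:
                    continue
                if b1 not in end_sets[i] or b2 not in end_sets[j]:
                    continue
                m1, m2 = og.meta[b1], og.meta[b2]
                if m1.fp_contig is None or m1.fp_contig != m2.fp_contig:
                    continue
                if cm_distance(og.anchors[b1], og.anchors[b2]) > 1.0:
                    continue
                candidates.append(
                    Candidate(
                        ((min(b1, b2), max(b1, b2)),), min(w1, w2), "linkBAC"
                    )
                )
    return candidates


def _propose_step7(og, ev):
    """Singleton bridges: a singleton B3 with stringent overlaps to BACs of
    two clusters on the same FP contig, within 3 cM of both."""
    comps, which = _cluster_index(og)
    singles = set(og.singletons())
    partners: dict[str, list[tuple[str, float]]] = {}
    for (a, b), call in ev.calls.items():
        if call.klass != "stringent":
            continue
        for b3, other in ((a, b), (b, a)):
            if b3 not in singles or not og.g.has_node(other):
                continue
            if other in singles:
                continue
            if not _extent_fraction_ok(
                call, og.meta[b3].length, og.meta[other].length, 0.10
            ):
                continue
            if cm_distance(og.anchors[b3], og.anchors[other]) > 3.0:
                continue
            partners.setdefault(b3, []).append((other, _edge_weight(call)))
    candidates = []
    for b3, plist in sorted(partners.items()):
        for x in range(len(plist)):
            for y in range(x + 1, len(plist)):
                (b1, w1), (b2, w2) = plist[x], plist[y]
                if which[b1] == which[b2]:
                    continue
                m1, m2 = og.meta[b1], og.meta[b2]
                if m1.fp_contig is None or m1.fp_contig != m2.fp_contig:
                    continue
                candidates.append(
                    Candidate(
                        ((b3, b1), (b3, b2)), min(w1, w2), "singleton-bridge"
                    )
                )
    return candidates


def _propose_step8(og, ev):
    """FP-contig + OM joins between the abutting ends of two clusters."""
    candidates = []
    for comp_a, comp_b, _ in _om_joined_pairs(og, ev):
        best = None
        for a in sorted(og.ends(comp_a)):
            for b in sorted(og.ends(comp_b)):
                ma, mb = og.meta[a], og.meta[b]
                if ma.fp_contig is None or ma.fp_contig != mb.fp_contig:
                    continue
                gap = abs((ma.fp_band or 0) - (mb.fp_band or 0)) * BAND_KB * 1000
                if gap > 300_000:
                    continue
                if best is None or gap < best[0]:
                    best = (gap, a, b)
        if best is not None:
            gap, a, b = best
            candidates.append(Candidate(((a, b),), -gap, "FP-bridge"))
    return candidates


def _propose_step9(og, ev):
    """Reinstate BACs excluded only for high cM spread (all WGS hits on one
    chromosome), attaching them by their stringent overlaps."""
    if ev.wgs_hits is None or ev.wgs_hits.empty:
        return []
    comps, which = _cluster_index(og)
    non_singleton = {n for c in comps if len(c) > 1 for n in c}
    candidates = []
    flagged = sorted(
        b for b, r in og.excluded.items() if r == "inconsistent_anchor"
    )
    for bac in flagged:
        hits = ev.wgs_hits[ev.wgs_hits["bac"] == bac]
        if hits.empty or hits["chrom"].nunique() != 1:
            continue
        edges = []
        weight = 0.0
        for (a, b), call in ev.calls.items():
            if call.klass != "stringent" or bac not in (a, b):
                continue
            other = b if a == bac else a
            if other in non_singleton:
                edges.append((bac, other))
                weight += _edge_weight(call)
        if edges:
            candidates.append(
                Candidate(tuple(sorted(edges)), weight, "reinstated", (bac,))
            )
    return candidates


def _propose_step10(og, ev):
    """Overlap + OM: permissive overlaps (>=10%) between end BACs of
    OM-joined clusters, within 3 cM."""
    candidates = []
    for comp_a, comp_b, _ in _om_joined_pairs(og, ev):
        for a in sorted(og.ends(comp_a)):
            for b in sorted(og.ends(comp_b)):
                call = ev.call(a, b)
                if call is None or call.klass == "none":
                    continue
                if not _extent_fraction_ok(
                    call, og.meta[a].length, og.meta[b].length, 0.10
                ):
                    continue
                if cm_distance(og.anchors[a], og.anchors[b]) > 3.0:
                    continue
                candidates.append(
                    Candidate(((a, b),), _edge_weight(call), "OM")
                )
    return candidates


def _propose_step11(og, ev):
    """FP-gap bridges: end BACs B1, B2 on one FP contig with exactly one
    BAC between them in the band order, OM-joined clusters."""
    fp_members: dict[str, list[tuple[float, str]]] = {}
    for b, m in og.meta.items():
        if m.fp_contig is not None and m.fp_band is not None:
            fp_members.setdefault(m.fp_contig, []).append((m.fp_band, b))
    for v in fp_members.values():
        v.sort()
    om_pairs = {
        (min(min(a), min(b)), max(min(a), min(b)))
        for a, b, _ in _om_joined_pairs(og, ev)
    }
    comps, which = _cluster_index(og)
    candidates = []
    seen = set()
    for comp_a, comp_b, _ in _om_joined_pairs(og, ev):
        for b1 in sorted(og.ends(comp_a)):
            for b2 in sorted(og.ends(comp_b)):
                key = (min(b1, b2), max(b1, b2))
                if key in seen:
                    continue
                m1, m2 = og.meta[b1], og.meta[b2]
                if m1.fp_contig is None or m1.fp_contig != m2.fp_contig:
                    continue
                if cm_distance(og.anchors[b1], og.anchors[b2]) > 3.0:
                    continue
                lo, hi = sorted((m1.fp_band or 0, m2.fp_band or 0))
                if (hi - lo) * BAND_KB * 1000 >= 300_000:
                    continue
                between = [
                    b
                    for band, b in fp_members[m1.fp_contig]
                    if lo < band < hi and b not in (b1, b2)
                ]
                if len(between) != 1:
                    continue
                seen.add(key)
                candidates.append(
                    Candidate((key,), -(hi - lo), "FP-bridge")
                )
    return candidates


# ---------------------------------------------------------------------------
# full refinement


def run_refinement(
    meta: dict[str, BacMeta],
    overlap_calls,
    anchors: dict[str, BacAnchor],
    evidence: RefinementEvidence,
    steps: range = range(1, 13),
) -> tuple[OverlapGraph, pd.DataFrame]:
    """Execute refinement steps 1-12 in order; returns the final graph and
    a per-step statistics table. Steps whose evidence tables are absent
    contribute no candidates (logged as skipped)."""
    og = build_initial_graph(meta, overlap_calls, anchors)
    rows = [og.stats(1)]
    for step in steps:
        if step == 1:
            continue
        if step == 2:
            step2_add_links(og, evidence)
        else:
            needs_om = step in (3, 4, 8, 10, 11, 12)
            needs_bes = step in (4, 5, 12)
            if needs_om and (evidence.om is None or evidence.om.empty):
                log.warning("step %d skipped: no optical-map table", step)
                rows.append(og.stats(step))
                continue
            if needs_bes and (evidence.bes is None or evidence.bes.empty):
                log.warning("step %d skipped: no BES table", step)
                rows.append(og.stats(step))
                continue
            candidates = propose_joins(og, step, evidence)
            add_edges_with_rollback(og, candidates, step)
        og.assert_invariants()
        rows.append(og.stats(step))
    return og, pd.DataFrame(rows)
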