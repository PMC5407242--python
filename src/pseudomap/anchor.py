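"""Genetic anchoring: genotype-matrix filtering, consensus-map merging and
majority-rule placement of BACs and BAC clusters on the genetic map.

A BAC is anchored by the WGS contigs aligning to it (alignments pre-filtered
at identity >= 99.8% and length >= 1 kb): at least 90% of its distinct
aligned contigs must come from one chromosome and the standard deviation of
their cM positions must be <= 3 cM; the anchor position is the median cM of
the modal-chromosome hits. Clusters aggregate member anchors the same way
with a 5 cM standard-deviation ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

ANCHORED = "anchored"
UNANCHORED = "unanchored"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class MapPosition:
    chrom: str
    cm: float


@dataclass(frozen=True)
class BacAnchor:
    bac: str
    status: str  # anchored | unanchored | inconsistent
    position: MapPosition | None = None

    @property
    def chrom(self) -> str | None:
        return self.position.chrom if self.position else None

    @property
    def cm(self) -> float | None:
        return self.position.cm if self.position else None


def _sd(values: np.ndarray) -> float:
    """Sample standard deviation; 0 for a single observation."""
    if values.size <= 1:
        return 0.0
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# genotype-matrix filtering


def filter_genotype_matrix(
    calls: pd.DataFrame,
    depth: pd.DataFrame,
    qual: pd.DataFrame,
    site_qual: pd.Series,
    profile: str,
    min_sample_calls: int = 6_000,
) -> pd.DataFrame:
    """Filter a calls matrix (markers x samples; 0=ref hom, 1=het,
    2=alt hom, -1=missing) under one of two named profiles.

    popseq — homozygous calls are set to missing at depth 0 or genotype
    quality < 3; heterozygous calls at depth < 3 or quality < 5; variants
    are dropped at site quality < 40, > 10% heterozygous calls, > 90%
    missing data, or minor allele frequency < 5%.

    gbs — site quality >= 40 required (bi-allelic input assumed);
    homozygous calls are set to missing at depth < 2 or quality < 20;
    heterozygous calls are ignored (set missing); variants with > 50%
    missing data or MAF < 30% are dropped; samples with fewer than
    ``min_sample_calls`` successful calls are dropped; finally SNPs with
    > 10% missing data are dropped.
    """
    c = calls.to_numpy().copy()
    d = depth.reindex_like(calls).to_numpy()
    q = qual.reindex_like(calls).to_numpy()
    sq = site_qual.reindex(calls.index).to_numpy()
    hom = (c == 0) | (c == 2)
    het = c == 1
    if profile == "popseq":
        c[hom & ((d == 0) | (q < 3))] = -1
        c[het & ((d < 3) | (q < 5))] = -1
        keep = sq >= 40
        n = c.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            nonmiss = (c >= 0).sum(axis=1)
            het_frac = np.divide((c == 1).sum(axis=1), np.maximum(nonmiss, 1))
            keep &= het_frac <= 0.10
            keep &= (c < 0).sum(axis=1) <= 0.90 * n
            keep &= _maf(c) >= 0.05
        return pd.DataFrame(c, index=calls.index, columns=calls.columns)[keep]
    if profile == "gbs":
        c[hom & ((d < 2) | (q < 20))] = -1
        c[het] = -1
        keep = sq >= 40
        keep &= (c < 0).sum(axis=1) <= 0.50 * c.shape[1]
        keep &= _maf(c) >= 0.30
        out = pd.DataFrame(c, index=calls.index, columns=calls.columns)[keep]
        sample_ok = (out.to_numpy() >= 0).sum(axis=0) >= min_sample_calls
        out = out.loc[:, sample_ok]
        if out.shape[1]:
            snp_ok = (out.to_numpy() < 0).sum(axis=1) <= 0.10 * out.shape[1]
            out = out[snp_ok]
        return out
    raise ValueError(f"unknown genotype filtering profile: {profile!r}")


def _maf(c: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant from a calls matrix."""
    ref = 2 * (c == 0).sum(axis=1) + (c == 1).sum(axis=1)
    alt = 2 * (c == 2).sum(axis=1) + (c == 1).sum(axis=1)
    tot = np.maximum(ref + alt, 1)
    f = ref / tot
    return np.minimum(f, 1 - f)


# ---------------------------------------------------------------------------
# consensus map merging


def merge_consensus_map(
    map_primary: pd.DataFrame,
    map_secondary: pd.DataFrame,
    max_disagreement_cm: float = 5.0,
    lowess_frac: float = 0.3,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Merge two genetic maps (columns: contig, chrom, cm) into a consensus.

    Per chromosome, a locally weighted linear regression of primary cM on
    secondary cM is fitted over shared contigs and used to interpolate
    secondary-only contigs into the primary scale. Contigs present in both
    maps whose positions disagree by more than ``max_disagreement_cm`` after
    interpolation are left unanchored; otherwise the primary position wins.
    Returns columns (contig, chrom, cm, status).
    """
    prim = map_primary.set_index("contig")
    sec = map_secondary.set_index("contig")
    rows = []
    chroms = sorted(set(prim["chrom"]) | set(sec["chrom"]))
    for chrom in chroms:
        p = prim[prim["chrom"] == chrom]
        s = sec[sec["chrom"] == chrom]
        shared = p.index.intersection(s.index)
        if len(shared) < min_shared:
            log.warning(
                "chromosome %s has only %d shared contigs (<%d); "
                "secondary-only contigs left unanchored",
                chrom, len(shared), min_shared,
            )
            for contig in p.index:
                rows.append((contig, chrom, float(p.loc[contig, "cm"]), ANCHORED))
            for contig in s.index.difference(p.index):
                rows.append((contig, chrom, np.nan, UNANCHORED))
            continue
        x = s.loc[shared, "cm"].to_numpy(float)
        y = p.loc[shared, "cm"].to_numpy(float)
        fit = lowess(y, x, frac=lowess_frac, return_sorted=True)
        fx, fy = fit[:, 0], fit[:, 1]

        def interp(v: np.ndarray) -> np.ndarray:
            return np.interp(v, fx, fy)

        # consistency of shared contigs: compare each contig's primary
        # position against a leave-one-out interpolation of its secondary
        # position, so a discordant contig cannot vouch for itself
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        pred_sorted = np.empty_like(ys)
        for k in range(xs.size):
            xk = np.delete(xs, k)
            yk = np.delete(ys, k)
            if xs[k] <= xk[0] or xs[k] >= xk[-1]:
                # end point: extrapolate linearly from the two nearest
                # neighbours rather than clamping
                i0, i1 = (0, 1) if xs[k] <= xk[0] else (-2, -1)
                dx = xk[i1] - xk[i0]
                slope = (yk[i1] - yk[i0]) / dx if dx else 0.0
                pred_sorted[k] = yk[i0] + slope * (xs[k] - xk[i0])
            else:
                pred_sorted[k] = np.interp(xs[k], xk, yk)
        pred = np.empty_like(pred_sorted)
        pred[order] = pred_sorted
        disagreement = np.abs(pred - y)
        for contig, bad in zip(shared, disagreement > max_disagreement_cm):
            if bad:
                rows.append((contig, chrom, np.nan, UNANCHORED))
            else:
                rows.append((contig, chrom, float(p.loc[contig, "cm"]), ANCHORED))
        for contig in p.index.difference(s.index):
            rows.append((contig, chrom, float(p.loc[contig, "cm"]), ANCHORED))
        only_sec = s.index.difference(p.index)
        if len(only_sec):
            vals = interp(s.loc[only_sec, "cm"].to_numpy(float))
            for contig, v in zip(only_sec, vals):
                rows.append((contig, chrom, float(v), ANCHORED))
    return pd.DataFrame(rows, columns=["contig", "chrom", "cm", "status"])


# ---------------------------------------------------------------------------
# BAC anchoring


def anchor_bac(
    bac: str,
    hits: pd.DataFrame,
    majority: float = 0.90,
    max_sd_cm: float = 3.0,
) -> BacAnchor:
    """Majority-rule anchor from WGS-contig hits (columns: wgs_contig,
    chrom, cm); distinct contigs are counted, ties break to inconsistent."""
    hits = hits.drop_duplicates("wgs_contig")
    if hits.empty:
        return BacAnchor(bac, UNANCHORED)
    counts = hits["chrom"].value_counts()
    top = counts.max()
    modal = sorted(counts[counts == top].index)
    if len(modal) > 1:
        return BacAnchor(bac, INCONSISTENT)
    chrom = modal[0]
    if top / len(hits) < majority:
        return BacAnchor(bac, INCONSISTENT)
    cms = hits.loc[hits["chrom"] == chrom, "cm"].to_numpy(float)
    if _sd(cms) > max_sd_cm:
        return BacAnchor(bac, INCONSISTENT)
    return BacAnchor(bac, ANCHORED, MapPosition(chrom, float(np.median(cms))))


def anchor_all_bacs(
    wgs_hits: pd.DataFrame, wgs_map: pd.DataFrame, bac_ids: list[str]
) -> dict[str, BacAnchor]:
    """Anchor every BAC in ``bac_ids`` from a hits table (wgs_contig, bac)
    joined against the map (wgs_contig, chrom, cm)."""
    merged = wgs_hits.merge(wgs_map, on="wgs_contig", how="inner")
    grouped = dict(tuple(merged.groupby("bac")))
    empty = pd.DataFrame(columns=["wgs_contig", "chrom", "cm"])
    return {b: anchor_bac(b, grouped.get(b, empty)) for b in bac_ids}


def rescue_via_neighbors(
    anchors: dict[str, BacAnchor],
    overlap_calls,
    lengths: dict[str, int],
    max_length: int = 300_000,
    min_overlap_fraction: float = 0.10,
    max_sd_cm: float = 3.0,
) -> dict[str, BacAnchor]:
    """Borrow positions for unanchored BACs from their overlap neighbours.

    Neighbours share >= 10% of either clone's assembled length. A BAC
    <= 300 kb whose neighbours are all anchored to one chromosome with cM
    standard deviation <= 3 is placed at their arithmetic mean. Single
    pass: rescued BACs never feed later rescues, and anchored BACs are
    never modified.
    """
    neighbors: dict[str, list[str]] = {}
    for call in overlap_calls:
        a, b = call.bac_a, call.bac_b
        if (
            call.extent_a >= min_overlap_fraction * lengths.get(a, np.inf)
            or call.extent_b >= min_overlap_fraction * lengths.get(b, np.inf)
        ):
            neighbors.setdefault(a, []).append(b)
            neighbors.setdefault(b, []).append(a)
    out = dict(anchors)
    for bac, anc in anchors.items():
        if anc.status != UNANCHORED or lengths.get(bac, np.inf) > max_length:
            continue
        nb = [anchors[n] for n in neighbors.get(bac, []) if n in anchors]
        nb_anchored = [a for a in nb if a.status == ANCHORED]
        if not nb_anchored or len(nb_anchored) != len(nb):
            continue
        chroms = {a.chrom for a in nb_anchored}
        if len(chroms) != 1:
            continue
        cms = np.array([a.cm for a in nb_anchored], float)
        if _sd(cms) > max_sd_cm:
            continue
        out[bac] = BacAnchor(
            bac, ANCHORED, MapPosition(chroms.pop(), float(np.mean(cms)))
        )
    return out


# ---------------------------------------------------------------------------
# cluster anchoring


@dataclass(frozen=True)
class ClusterAnchor:
    status: str
    position: MapPosition | None = None

    @property
    def chrom(self) -> str | None:
        return self.position.chrom if self.position else None

    @property
    def cm(self) -> float | None:
        return self.position.cm if self.position else None


def anchor_cluster(
    member_anchors: list[BacAnchor], max_sd_cm: float = 5.0
) -> ClusterAnchor:
    """Aggregate member anchors: all anchored members must agree on one
    chromosome with cM standard deviation <= 5; position is the median."""
    anchored = [a for a in member_anchors if a.status == ANCHORED]
    if not anchored:
        return ClusterAnchor(UNANCHORED)
    chroms = {a.chrom for a in anchored}
    if len(chroms) != 1:
        return ClusterAnchor(INCONSISTENT)
    cms = np.array([a.cm for a in anchored], float)
    if _sd(cms) > max_sd_cm:
        return ClusterAnchor(INCONSISTENT)
    return ClusterAnchor(
        ANCHORED, MapPosition(chroms.pop(), float(np.median(cms)))
    )
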