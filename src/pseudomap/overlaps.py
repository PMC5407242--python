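"""Pairwise BAC overlap detection and classification.

BAC assemblies are aligned all-against-all; each unordered BAC pair is then
classified from its HSPs:

* stringent  — at least one HSP with length >= 5 kb and identity >= 99.8%
* permissive — at least one HSP with length >= 2 kb and identity >= 99.5%
* none       — otherwise

For classified pairs the overlap *extent* is the total non-redundant length
covered by qualifying HSPs (length >= 500 bp, identity >= 99.5%) projected
onto each BAC's own sequences, after combining intervals less than 200 bp
apart. Extents are reported per BAC, since the two BACs of a pair may have
different assembled representations of the shared region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .align import Hsp, align_pairwise, frame_to_hsps, hsps_to_frame
from .intervals import union_length

STRINGENT_LENGTH, STRINGENT_IDENTITY = 5_000, 99.8
PERMISSIVE_LENGTH, PERMISSIVE_IDENTITY = 2_000, 99.5
EXTENT_MIN_LENGTH, EXTENT_MIN_IDENTITY = 500, 99.5
EXTENT_MERGE_GAP = 200


def bac_of(record_name: str) -> str:
    """BAC id of a scaffold record named '<bac>.s<j>'."""
    return record_name.rsplit(".s", 1)[0]


@dataclass(frozen=True)
class OverlapCall:
    bac_a: str  # bac_a < bac_b lexicographically
    bac_b: str
    klass: str  # 'stringent' | 'permissive' | 'none'
    extent_a: int  # merged overlap bp on bac_a's sequences
    extent_b: int

    def extent_on(self, bac: str) -> int:
        if bac == self.bac_a:
            return self.extent_a
        if bac == self.bac_b:
            return self.extent_b
        raise KeyError(bac)


def align_assemblies(
    bac_fastas: Mapping[str, str],
    min_identity: float = 99.0,
    min_length: int = 500,
    hsp_table: pd.DataFrame | None = None,
    **aligner_kwargs,
) -> pd.DataFrame:
    """HSP table (12-column BLAST dialect) of the BAC set against itself.

    ``bac_fastas`` maps scaffold record names ('<bac>.s<j>') to sequences.
    If ``hsp_table`` is given (externally produced BLAST tabular output) it
    is filtered to the thresholds and returned instead of aligning.
    """
    if hsp_table is not None:
        df = hsp_table
        df = df[(df["identity"] >= min_identity) & (df["length"] >= min_length)]
        return df.reset_index(drop=True)
    hsps = align_pairwise(
        bac_fastas,
        bac_fastas,
        min_identity=min_identity,
        min_length=min_length,
        **aligner_kwargs,
    )
    return hsps_to_frame(hsps)


def classify_pair(hsps: Iterable[Hsp]) -> str:
    """Overlap class of one unordered BAC pair from its HSPs."""
    best = "none"
    for h in hsps:
        if h.length >= STRINGENT_LENGTH and h.identity >= STRINGENT_IDENTITY:
            return "stringent"
        if h.length >= PERMISSIVE_LENGTH and h.identity >= PERMISSIVE_IDENTITY:
            best = "permissive"
    return best


def overlap_extent(hsps: Iterable[Hsp]) -> dict[str, int]:
    """Non-redundant overlap extent per BAC for one BAC pair.

    Qualifying HSPs (>= 500 bp, >= 99.5% identity) are projected onto each
    BAC's scaffolds; per scaffold, intervals less than 200 bp apart are
    combined before summing. Projections from both orientations of the same
    alignment fall in the same union, so symmetric duplicate rows are
    harmless.
    """
    per_bac: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for h in hsps:
        if h.length < EXTENT_MIN_LENGTH or h.identity < EXTENT_MIN_IDENTITY:
            continue
        for record, iv in (
            (h.query, h.query_interval()),
            (h.subject, h.subject_interval()),
        ):
            per_bac.setdefault(bac_of(record), {}).setdefault(record, []).append(iv)
    return {
        bac: sum(
            union_length(ivs, max_gap=EXTENT_MERGE_GAP)
            for ivs in scaffolds.values()
        )
        for bac, scaffolds in per_bac.items()
    }


def compute_overlaps(hsp_table: pd.DataFrame) -> list[OverlapCall]:
    """Classify every BAC pair present in an HSP table.

    Self-hits (both records from one BAC) are dropped; symmetric rows are
    folded into one unordered pair.
    """
    hsps = frame_to_hsps(hsp_table)
    pairs: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        a, b = bac_of(h.query), bac_of(h.subject)
        if a == b:
            continue
        pairs.setdefault((min(a, b), max(a, b)), []).append(h)
    calls = []
    for (a, b), pair_hsps in sorted(pairs.items()):
        klass = classify_pair(pair_hsps)
        if klass == "none":
            continue
        extents = overlap_extent(pair_hsps)
        calls.append(
            OverlapCall(a, b, klass, extents.get(a, 0), extents.get(b, 0))
        )
    return calls


def calls_to_frame(calls: Iterable[OverlapCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.bac_a, c.bac_b, c.klass, c.extent_a, c.extent_b) for c in calls],
        columns=["bac_a", "bac_b", "class", "extent_a", "extent_b"],
    )
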