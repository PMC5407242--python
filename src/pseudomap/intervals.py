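"""Half-open interval arithmetic on sequence coordinates.

All intervals are 0-based half-open ``(start, end)`` tuples. These helpers
back overlap-extent computation, redundancy subtraction and masking; they are
deliberately simple list-based routines (inputs are per-sequence and small).
"""

from __future__ import annotations

from typing import Iterable


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge overlapping intervals; intervals separated by a gap strictly
    smaller than ``max_gap`` are combined into one.

    ``max_gap=0`` merges only touching/overlapping intervals; ``max_gap=200``
    combines intervals less than 200 bp apart.
    """
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    if not ivs:
        return []
    merged = [ivs[0]]
    for a, b in ivs[1:]:
        pa, pb = merged[-1]
        if a - pb < max_gap or a <= pb:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))
    return merged


def union_length(intervals: Iterable[tuple[int, int]], max_gap: int = 0) -> int:
    """Total length covered by the union of ``intervals`` (gaps < ``max_gap``
    count as covered, matching the merge rule)."""
    return sum(b - a for a, b in merge_intervals(intervals, max_gap=max_gap))


def subtract_intervals(
    keep: Iterable[tuple[int, int]], remove: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Subtract the union of ``remove`` from each interval in ``keep``."""
    removed = merge_intervals(remove)
    out: list[tuple[int, int]] = []
    for a, b in keep:
        cur = a
        for ra, rb in removed:
            if rb <= cur or ra >= b:
                continue
            if ra > cur:
                out.append((cur, min(ra, b)))
            cur = max(cur, rb)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def intersect_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
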