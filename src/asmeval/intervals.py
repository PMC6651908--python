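"""Half-open interval arithmetic on a single sequence.

All intervals are 0-based half-open ``(start, end)`` tuples with
``start < end``. Functions returning interval lists always return them
merged (non-overlapping, non-adjacent) and sorted by start.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or adjacent intervals into a sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    """Number of distinct positions covered by the intervals."""
    return sum(e - s for s, e in merge(intervals))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two interval lists (inputs need not be merged)."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Positions in ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Positions of ``[0, length)`` not covered by the intervals."""
    return subtract([(0, length)], intervals)


def to_mask(intervals: Iterable[Interval], length: int) -> np.ndarray:
    """Boolean coverage mask of the intervals over ``[0, length)``.

    Intended for brute-force cross-checks on small sequences; the
    interval-sweep functions above are the production path.
    """
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s):min(length, e)] = True
    return mask
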