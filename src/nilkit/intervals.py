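"""Closed-interval arithmetic on physical (bp) coordinates.

Intervals are closed ``[start, end]`` with ``start <= end``; coordinates are
the positions of the bounding markers. Set operations follow closure
semantics: the difference of two closed intervals is reported as the closure
of the open set difference, so subtracting ``[505086, 5273972]`` from
``[2040091, 19225223]`` yields ``[5273972, 19225223]`` — the excluded region
is bounded by the flanking marker itself.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[float, float]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or touching closed intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if a > b:
            raise ValueError(f"invalid interval [{a}, {b}]: start > end")
    merged: List[Interval] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def union(*interval_sets: Iterable[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for s in interval_sets:
        out.extend(s)
    return normalize(out)


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (closed; may return point intervals)."""
    xs, ys = normalize(a), normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        lo = max(xs[i][0], ys[j][0])
        hi = min(xs[i][1], ys[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Closure of the set difference a \\ b.

    Endpoints of the subtracted set remain as boundary coordinates of the
    result, so results abut the removed intervals at the removed endpoints.
    """
    xs, ys = normalize(a), normalize(b)
    out: List[Interval] = []
    for a0, a1 in xs:
        cur = a0
        for b0, b1 in ys:
            if b1 <= cur or b0 >= a1:
                if b0 >= a1:
                    break
                continue
            if b0 > cur:
                out.append((cur, b0))
            cur = max(cur, b1)
            if cur >= a1:
                break
        if cur < a1:
            out.append((cur, a1))
    # degenerate point-only leftovers at shared endpoints are kept out
    return [(a, b) for a, b in out if a < b]


def total_length_bp(intervals: Iterable[Interval]) -> int:
    """Total covered physical length, counting closed bp intervals as end-start+1."""
    return int(sum(b - a + 1 for a, b in normalize(intervals)))


def span_length(intervals: Iterable[Interval]) -> float:
    """Total covered length in continuous coordinates (end - start)."""
    return float(sum(b - a for a, b in normalize(intervals)))
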