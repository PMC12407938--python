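"""Half-open interval arithmetic on (start, end) integer pairs.

All functions take and return lists of ``(start, end)`` tuples with
``start < end``, 0-based half-open, on a single chromosome. Outputs are
sorted and non-overlapping.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sort and coalesce overlapping/adjacent-overlapping.

    Book-ended intervals ([0,5),[5,9)) are merged into one.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b. Both inputs may be unsorted/overlapping."""
    a = merge(a)
    b = merge(b)
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
    """Gaps of [0, length) not covered by the intervals."""
    return subtract([(0, length)], intervals)


def clip(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Intersect each interval with [0, length), dropping empties."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, 0), min(e, length)
        if s2 < e2:
            out.append((s2, e2))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def count_overlapping(regions: Sequence[Interval], features: Sequence[Interval]) -> list[int]:
    """For each region, the number of features it overlaps (features counted
    once per region, `bedtools intersect -c` semantics)."""
    return [sum(1 for f in features if overlaps(r, f)) for r in regions]


def covered_fraction(region: Interval, features: Sequence[Interval]) -> float:
    """Fraction of region bases covered by the union of the features."""
    s, e = region
    if e <= s:
        raise ValueError("empty region")
    inside = [(max(fs, s), min(fe, e)) for fs, fe in features if overlaps(region, (fs, fe))]
    return total_length(inside) / (e - s)
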