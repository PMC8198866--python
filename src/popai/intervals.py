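"""Half-open interval arithmetic used throughout the package.

All intervals are ``(start, end)`` tuples in seconds since recording start
with ``start < end``; interval lists are kept sorted and disjoint.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[float, float]


def normalize(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort, drop empties and merge touching/overlapping intervals."""
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def total_duration(intervals: Iterable[Interval]) -> float:
    return sum(b - a for a, b in normalize(intervals))


def intersect(xs: Iterable[Interval], ys: Iterable[Interval]) -> list[Interval]:
    xs, ys = normalize(xs), normalize(ys)
    out: list[Interval] = []
    i = j = 0
    while i < len(xs) and j < len(ys):
        a = max(xs[i][0], ys[j][0])
        b = min(xs[i][1], ys[j][1])
        if b > a:
            out.append((a, b))
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(xs: Iterable[Interval], ys: Iterable[Interval]) -> list[Interval]:
    """Set difference xs \\ ys."""
    xs, ys = normalize(xs), normalize(ys)
    out: list[Interval] = []
    for a, b in xs:
        cur = a
        for c, d in ys:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def clip(intervals: Iterable[Interval], t0: float, t1: float) -> list[Interval]:
    return intersect(intervals, [(t0, t1)])


def contains(intervals: Sequence[Interval], t: float) -> bool:
    return any(a <= t < b for a, b in intervals)
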