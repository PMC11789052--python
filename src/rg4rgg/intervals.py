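"""Half-open interval arithmetic on transcript coordinates."""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = [
    "merge_intervals",
    "total_length",
    "clip_intervals",
    "overlap_length",
    "jaccard",
    "containment",
]

Interval = tuple[int, int]


def merge_intervals(
    intervals: Iterable[Interval], join_adjacent: bool = True
) -> list[Interval]:
    """Sorted union of half-open intervals.

    ``join_adjacent`` merges abutting intervals (end == start) as well, so
    that adjacency counts as a single consecutive stretch — the convention
    used when testing for a run of consecutive overlapping nucleotides.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and (s < out[-1][1] or (join_adjacent and s == out[-1][1])):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    """Number of nucleotides covered by a union of intervals."""
    return sum(e - s for s, e in merge_intervals(intervals)) if intervals else 0


def clip_intervals(intervals: Iterable[Interval], span: Interval) -> list[Interval]:
    """Intersect each interval with ``span``; empty results are dropped."""
    lo, hi = span
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the intersection of two half-open intervals (>= 0)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _intersection_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    a = merge_intervals(a) if a else []
    b = merge_intervals(b) if b else []
    i = j = inter = 0
    while i < len(a) and j < len(b):
        inter += overlap_length(a[i], b[j])
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return inter


def jaccard(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Nucleotide-level Jaccard index of two interval sets (1.0 if both empty)."""
    inter = _intersection_length(a, b)
    union = total_length(list(a)) + total_length(list(b)) - inter
    return inter / union if union else 1.0


def containment(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Fraction of the nucleotides of ``a`` that lie inside ``b`` (0.0 if ``a`` empty)."""
    la = total_length(list(a))
    return _intersection_length(a, b) / la if la else 0.0
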