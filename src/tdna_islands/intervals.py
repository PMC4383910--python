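"""Topology-aware genomic interval arithmetic.

Internal convention: 0-based, half-open, forward-strand coordinates.
On a circular replicon an interval with ``start > end`` wraps across the
origin, i.e. it covers ``[start, L) ∪ [0, end)``.  ``start == end`` is not a
valid interval (no zero-length features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Tuple


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, possibly wrapping the origin of a circular replicon."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in interval ({self.start}, {self.end})")
        if self.start == self.end:
            raise ValueError("zero-length interval")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, replicon_length: int | None = None) -> int:
        """Span in bp; wrapping intervals need the replicon length."""
        if not self.wraps:
            return self.end - self.start
        if replicon_length is None:
            raise ValueError("replicon_length required for a wrapping interval")
        return replicon_length - self.start + self.end

    def segments(self, replicon_length: int | None = None) -> Iterator[Tuple[int, int]]:
        """Non-wrapping (start, end) pieces covering the interval, in 5'->3' order."""
        if not self.wraps:
            yield (self.start, self.end)
        else:
            if replicon_length is None:
                raise ValueError("replicon_length required for a wrapping interval")
            yield (self.start, replicon_length)
            if self.end > 0:
                yield (0, self.end)

    def contains_point(self, pos: int) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start},{self.end})"


def _seg_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo)


def overlap_length(a: Interval, b: Interval, replicon_length: int | None = None) -> int:
    """Number of positions shared by two intervals (topology-aware)."""
    total = 0
    for sa in a.segments(replicon_length):
        for sb in b.segments(replicon_length):
            total += _seg_overlap(sa, sb)
    return total


def overlaps(a: Interval, b: Interval, replicon_length: int | None = None) -> bool:
    return overlap_length(a, b, replicon_length) > 0


def contains(outer: Interval, inner: Interval, replicon_length: int | None = None) -> bool:
    """True if *inner* is fully contained in *outer*."""
    inner_len = inner.length(replicon_length)
    return overlap_length(outer, inner, replicon_length) == inner_len


def shift(iv: Interval, offset: int, replicon_length: int, circular: bool) -> Interval:
    """Translate an interval by ``offset`` (rotation on circular replicons)."""
    if not circular:
        return Interval(iv.start + offset, iv.end + offset)
    s = (iv.start + offset) % replicon_length
    e = (iv.end + offset) % replicon_length
    if e == 0:
        e = replicon_length
    return Interval(s, e)


def mirror(iv: Interval, replicon_length: int) -> Interval:
    """Interval position after reverse-complementing the whole replicon."""
    if not iv.wraps:
        return Interval(replicon_length - iv.end, replicon_length - iv.start)
    # wrapping [s, L) u [0, e) mirrors to wrapping [L-e, L) u [0, L-s)
    return Interval(replicon_length - iv.end, replicon_length - iv.start)


def forward_gap(from_pos: int, to_pos: int, replicon_length: int, circular: bool) -> int | None:
    """Distance walking 5'->3' on the forward strand from one position to another.

    Returns None when the walk is impossible on a linear replicon.
    """
    if to_pos >= from_pos:
        return to_pos - from_pos
    if not circular:
        return None
    return replicon_length - from_pos + to_pos


def slice_sequence(sequence: str, iv: Interval) -> str:
    """Extract the interval's forward-strand sequence (joining across the origin)."""
    return "".join(sequence[s:e] for s, e in iv.segments(len(sequence)))
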