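"""Sorted, non-overlapping half-open time intervals.

The kinematic pipeline reasons about time as unions of half-open
intervals ``[start, end)``: open-door periods, nose-in-zone bouts, FR
bins. :class:`IntervalSet` normalises its input (sorts, merges
overlapping and touching intervals) so set algebra — intersection,
union, complement within a span — is exact and closed under the class
invariants.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np

__all__ = ["IntervalSet"]


class IntervalSet:
    """An ordered union of disjoint half-open intervals ``[start, end)``."""

    __slots__ = ("starts", "ends")

    def __init__(self, intervals: Iterable[tuple[float, float]] = ()):
        pairs = [(float(s), float(e)) for s, e in intervals]
        for s, e in pairs:
            if not (s < e):
                raise ValueError(f"interval start must precede end: [{s}, {e})")
        pairs.sort()
        starts: list[float] = []
        ends: list[float] = []
        for s, e in pairs:
            if starts and s <= ends[-1]:  # overlap or touch: merge
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        self.starts = np.asarray(starts, dtype=float)
        self.ends = np.asarray(ends, dtype=float)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_mask(cls, mask: np.ndarray, fps: float) -> "IntervalSet":
        """Intervals covering the maximal True runs of a per-frame mask.

        Frame ``i`` occupies ``[i/fps, (i+1)/fps)``.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return cls()
        edges = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        return cls(zip(starts / fps, ends / fps))

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:
        body = ", ".join(f"[{s:g}, {e:g})" for s, e in self)
        return f"IntervalSet({body})"

    @property
    def total(self) -> float:
        """Total covered duration in seconds."""
        return float(np.sum(self.ends - self.starts))

    def contains(self, t: float) -> bool:
        i = np.searchsorted(self.starts, t, side="right") - 1
        return i >= 0 and t < self.ends[i]

    # -- algebra ---------------------------------------------------------
    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        while i < len(self) and j < len(other):
            s = max(self.starts[i], other.starts[j])
            e = min(self.ends[i], other.ends[j])
            if s < e:
                out.append((s, e))
            if self.ends[i] <= other.ends[j]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def complement(self, span: tuple[float, float]) -> "IntervalSet":
        """The gaps of this set within ``[span0, span1)``."""
        lo, hi = float(span[0]), float(span[1])
        if not lo < hi:
            raise ValueError("span start must precede span end")
        out = []
        cursor = lo
        for s, e in self:
            if e <= lo or s >= hi:
                continue
            if s > cursor:
                out.append((cursor, min(s, hi)))
            cursor = max(cursor, e)
        if cursor < hi:
            out.append((cursor, hi))
        return IntervalSet(out)

    def clip(self, span: tuple[float, float]) -> "IntervalSet":
        lo, hi = float(span[0]), float(span[1])
        return self.intersection(IntervalSet([(lo, hi)])) if lo < hi else IntervalSet()

    def shift(self, delta: float) -> "IntervalSet":
        return IntervalSet((s + delta, e + delta) for s, e in self)
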