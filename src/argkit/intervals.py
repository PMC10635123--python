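"""Ordered sets of disjoint half-open genomic intervals.

An :class:`IntervalSet` is the inheritance annotation attached to a gARG edge:
the genomic intervals over which a child genome inherits from a particular
parent.  All coordinates are 0-based, half-open ``[left, right)``.  The
canonical form is sorted, disjoint, and merges abutting intervals
(``right_i == left_{i+1}``), so equality of annotations is exact equality of
tuples.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

__all__ = ["IntervalSet"]

Interval = Tuple[float, float]


class IntervalSet:
    """An immutable, canonical set of disjoint half-open intervals.

    Parameters
    ----------
    intervals:
        Iterable of ``(left, right)`` pairs with ``left < right``.  Pairs may
        arrive unsorted, overlapping, or abutting; the constructor merges them
        into canonical form (union semantics).  Pairs with ``left == right``
        are dropped as empty.
    """

    __slots__ = ("_ivals",)

    def __init__(self, intervals: Iterable[Interval] = ()):
        pairs = []
        for left, right in intervals:
            if right < left:
                raise ValueError(f"interval has right < left: [{left}, {right})")
            if left < right:
                pairs.append((float(left), float(right)))
        pairs.sort()
        merged: list[Interval] = []
        for left, right in pairs:
            if merged and left <= merged[-1][1]:
                if right > merged[-1][1]:
                    merged[-1] = (merged[-1][0], right)
            else:
                merged.append((left, right))
        self._ivals = tuple(merged)

    # -- constructors -------------------------------------------------------

    @classmethod
    def single(cls, left: float, right: float) -> "IntervalSet":
        return cls([(left, right)])

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    @classmethod
    def _wrap(cls, ivals: tuple) -> "IntervalSet":
        out = cls.__new__(cls)
        out._ivals = ivals
        return out

    # -- basic queries ------------------------------------------------------

    @property
    def intervals(self) -> tuple:
        return self._ivals

    @property
    def span(self) -> float:
        """Total genomic length covered."""
        return sum(r - l for l, r in self._ivals)

    def __bool__(self) -> bool:
        return bool(self._ivals)

    def __len__(self) -> int:
        return len(self._ivals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._ivals)

    def __contains__(self, x: float) -> bool:
        for l, r in self._ivals:
            if l <= x < r:
                return True
            if x < l:
                return False
        return False

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._ivals == other._ivals

    def __hash__(self) -> int:
        return hash(self._ivals)

    def __repr__(self) -> str:
        body = ", ".join(f"[{l:g}, {r:g})" for l, r in self._ivals)
        return "{" + body + "}"

    @property
    def left(self) -> float:
        """Leftmost coordinate; raises on an empty set."""
        return self._ivals[0][0]

    @property
    def right(self) -> float:
        """Rightmost coordinate; raises on an empty set."""
        return self._ivals[-1][1]

    # -- set algebra --------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        if not other:
            return self
        if not self:
            return other
        return IntervalSet(self._ivals + other._ivals)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        if not self or not other:
            return IntervalSet._wrap(())
        out = []
        a, b = self._ivals, other._ivals
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if lo < hi:
                out.append((lo, hi))
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet._wrap(tuple(out))

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        if not self or not other:
            return self
        out = []
        b = other._ivals
        for l, r in self._ivals:
            cur = l
            for bl, br in b:
                if br <= cur:
                    continue
                if bl >= r:
                    break
                if bl > cur:
                    out.append((cur, bl))
                cur = max(cur, br)
                if cur >= r:
                    break
            if cur < r:
                out.append((cur, r))
        return IntervalSet._wrap(tuple(out))

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def issubset(self, other: "IntervalSet") -> bool:
        return not self.difference(other)
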