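"""Closed-interval algebra used by substitution mapping and fine mapping.

Intervals are closed ``[start, end]`` on a single linear coordinate axis
(centimorgans or base pairs — the algebra is unit-agnostic).  Negative
evidence removes only the *interior* of an interval, so a shared endpoint
survives subtraction: ``[0, 10] - [0, 6] -> [0, 0], [6, 10]``.  Degenerate
single-point remainders are kept; callers that report lengths may filter
them with :func:`drop_degenerate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConflictError, InputError


@dataclass(frozen=True, order=True)
class Interval:
    start: float
    end: float

    def __post_init__(self):
        if self.end < self.start:
            raise InputError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, x: float) -> bool:
        return self.start <= x <= self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        """Closed-interval overlap; touching endpoints count."""
        return self.start <= other.end and other.start <= self.end

    def intersect(self, other: "Interval") -> "Interval | None":
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return Interval(lo, hi) if lo <= hi else None


def intersect_all(intervals: Sequence[Interval]) -> Interval | None:
    if not intervals:
        raise InputError("cannot intersect an empty interval collection")
    acc: Interval | None = intervals[0]
    for iv in intervals[1:]:
        if acc is None:
            return None
        acc = acc.intersect(iv)
    return acc


def subtract_interior(piece: Interval, cut: Interval) -> list[Interval]:
    """Remove the open interior of ``cut`` from ``piece``."""
    if cut.length == 0 or cut.start >= piece.end or cut.end <= piece.start:
        # empty interior, or interior misses the piece (touching is fine)
        return [piece]
    out: list[Interval] = []
    if cut.start >= piece.start:
        out.append(Interval(piece.start, cut.start))
    if cut.end <= piece.end:
        out.append(Interval(cut.end, piece.end))
    return out


def subtract_all(base: Iterable[Interval], cuts: Iterable[Interval]) -> list[Interval]:
    pieces = list(base)
    for cut in cuts:
        nxt: list[Interval] = []
        for p in pieces:
            nxt.extend(subtract_interior(p, cut))
        pieces = nxt
    return sorted(pieces)


def drop_degenerate(intervals: Iterable[Interval]) -> list[Interval]:
    return [iv for iv in intervals if iv.length > 0]


def localize(
    positives: Sequence[Interval],
    negatives: Sequence[Interval],
    member_ids: Sequence[str] = (),
) -> list[Interval]:
    """Intersect positive evidence, then subtract negative-evidence interiors.

    Raises :class:`ConflictError` when the positive intersection is empty or
    when subtraction erases every candidate point.
    """
    core = intersect_all(positives)
    if core is None:
        raise ConflictError(
            f"positive evidence intervals do not intersect: {list(member_ids) or list(positives)}",
            members=member_ids,
        )
    pieces = subtract_all([core], negatives)
    if not pieces:
        raise ConflictError(
            "negative evidence removed the entire candidate region",
            members=member_ids,
        )
    return pieces
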