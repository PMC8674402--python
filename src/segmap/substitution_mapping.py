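"""Integration of per-line detections into QTLs by interval algebra.

Lines that detect a QTL and whose maximal segment intervals overlap on the
same chromosome with the same effect sign are one locus; the locus is then
localized to the intersection of the members' maximal intervals minus the
interiors of the core intervals of overlapping lines that did *not* detect
it.  Loci are named ``q<TAG><chrom><letter>`` ordered from the short-arm end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .intervals import Interval, drop_degenerate, intersect_all, localize
from .sssl_core import DetectionResult, SubstitutedSegment

__all__ = [
    "QTLGroup",
    "IntegratedQTL",
    "group_detections",
    "localize_qtl",
    "summarize_group",
    "integrate_detections",
]


@dataclass
class QTLGroup:
    name: str
    chromosome: str
    members: list[DetectionResult]
    segments: list[SubstitutedSegment]
    sign: int

    def __post_init__(self):
        if len({seg.chromosome for seg in self.segments}) > 1:
            raise InputError("group members span multiple chromosomes")

    @property
    def member_ids(self) -> list[str]:
        return [m.line_id for m in self.members]

    def intersection(self) -> Interval | None:
        return intersect_all([seg.maximal for seg in self.segments])


@dataclass
class IntegratedQTL:
    name: str
    chromosome: str
    donors: list[str]
    intervals: list[Interval]
    a_mean: float
    a_sd: float
    r2_mean: float
    r2_sd: float
    member_ids: list[str]
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return sum(iv.length for iv in self.intervals)


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except (TypeError, ValueError):
        return (1, str(chrom))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_detections(
    detections: list[DetectionResult],
    segments: dict[str, SubstitutedSegment],
    trait_tag: str = "QTL",
) -> list[QTLGroup]:
    """Connected components of the same-chromosome, same-sign overlap graph.

    Overlap is tested on maximal intervals (closed).  Output order and names
    are independent of input order: groups are sorted by chromosome and by
    the start of the members' interval intersection, and lettered a, b, ...
    within a chromosome only when it carries more than one locus.
    """
    missing = [d.line_id for d in detections if d.line_id not in segments]
    if missing:
        raise InputError(f"detections without a segment: {missing}")

    dets = sorted(detections, key=lambda d: d.line_id)
    uf = _UnionFind(len(dets))
    for i in range(len(dets)):
        si = segments[dets[i].line_id]
        for j in range(i + 1, len(dets)):
            sj = segments[dets[j].line_id]
            if (
                si.chromosome == sj.chromosome
                and dets[i].sign == dets[j].sign
                and si.maximal.overlaps(sj.maximal)
            ):
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(dets)):
        components.setdefault(uf.find(i), []).append(i)

    raw: list[QTLGroup] = []
    for idxs in components.values():
        members = [dets[i] for i in idxs]
        segs = [segments[m.line_id] for m in members]
        raw.append(
            QTLGroup(
                name="",
                chromosome=segs[0].chromosome,
                members=members,
                segments=segs,
                sign=members[0].sign,
            )
        )

    def sort_key(g: QTLGroup):
        inter = g.intersection()
        start = inter.start if inter is not None else math.inf
        return (_chrom_key(g.chromosome), start, g.member_ids)

    raw.sort(key=sort_key)
    per_chrom: dict[str, list[QTLGroup]] = {}
    for g in raw:
        per_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, groups in per_chrom.items():
        for i, g in enumerate(groups):
            suffix = chr(ord("a") + i) if len(groups) > 1 else ""
            g.name = f"q{trait_tag}{chrom}{suffix}"
    return raw


def localize_qtl(
    group: QTLGroup,
    nonsignificant: list[tuple[str, SubstitutedSegment]] = (),
) -> list[Interval]:
    """Localized interval(s) for one integrated QTL.

    Result = intersection of member maximal intervals minus the interiors of
    core intervals of non-significant lines whose maximal interval overlaps a
    member's.  Raises :class:`ConflictError` on empty evidence.
    """
    if not group.members:
        raise InputError("empty group")
    positives = [seg.maximal for seg in group.segments]
    negatives = []
    for _, seg in nonsignificant:
        if seg.chromosome != group.chromosome:
            continue
        if any(seg.maximal.overlaps(m) for m in positives):
            negatives.append(seg.core)
    return localize(positives, negatives, member_ids=group.member_ids)


def _mean_sd(values: list[float], sds: list[float]) -> tuple[float, float]:
    if len(values) == 1:
        # single member: carry its season-averaged value and season SD through
        return values[0], sds[0]
    return float(np.mean(values)), float(np.std(values, ddof=1))


def summarize_group(
    group: QTLGroup,
    intervals: list[Interval] | None = None,
    excluded_ids: list[str] = (),
) -> IntegratedQTL:
    """Member-averaged effect summary (a Table-2-style row)."""
    if not group.members:
        raise InputError("empty group")
    a_mean, a_sd = _mean_sd(
        [m.a_mean for m in group.members], [m.a_sd for m in group.members]
    )
    r2_mean, r2_sd = _mean_sd(
        [m.r2_mean for m in group.members], [m.r2_sd for m in group.members]
    )
    donors = sorted({m.donor_id for m in group.members if m.donor_id})
    if intervals is None:
        inter = group.intersection()
        intervals = [inter] if inter is not None else []
    return IntegratedQTL(
        name=group.name,
        chromosome=group.chromosome,
        donors=donors,
        intervals=list(intervals),
        a_mean=a_mean,
        a_sd=a_sd,
        r2_mean=r2_mean,
        r2_sd=r2_sd,
        member_ids=group.member_ids,
        excluded_ids=list(excluded_ids),
    )


def integrate_detections(
    detections: list[DetectionResult],
    segments: dict[str, SubstitutedSegment],
    nonsignificant: list[tuple[str, SubstitutedSegment]] = (),
    trait_tag: str = "QTL",
) -> list[IntegratedQTL]:
    """Full pipeline: group, localize, summarize."""
    out = []
    for group in group_detections(detections, segments, trait_tag=trait_tag):
        pieces = drop_degenerate(localize_qtl(group, nonsignificant))
        used_negatives = [
            lid
            for lid, seg in nonsignificant
            if seg.chromosome == group.chromosome
            and any(seg.maximal.overlaps(s.maximal) for s in group.segments)
        ]
        out.append(summarize_group(group, pieces, excluded_ids=used_negatives))
    return out
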