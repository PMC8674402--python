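"""Core domain types and per-line QTL statistics for substitution-line panels.

A substitution line carries one homozygous donor segment in a recurrent
background, so a per-line QTL test is a two-sample comparison of germination
proportions between the line and the recurrent parent, season by season, on
arcsine-square-root transformed replicates.  Effects are estimated on the raw
proportion scale: the additive effect is half the line-parent difference and
the contribution is the additive effect relative to the parent mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    DomainError,
    InputError,
    UndefinedStatisticError,
)
from .intervals import Interval

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "SubstitutedSegment",
    "SSSLLine",
    "SeasonStats",
    "DetectionResult",
    "HeritabilityResult",
    "arcsine_transform",
    "detect_line_qtl",
    "estimate_effect",
    "estimate_H2",
    "anova_blocks",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention, e.g. 30.95 -> 31.0)."""
    q = Decimal(10) ** -ndigits
    # pre-quantize to absorb float representation error (28.349999... -> 28.35)
    d = Decimal(repr(x)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) per chromosome."""

    entries: list[tuple[str, str, float]]  # (marker, chromosome, cM)

    def __post_init__(self):
        seen: dict[str, tuple[str, float]] = {}
        by_chrom: dict[str, list[float]] = {}
        for marker, chrom, pos in self.entries:
            if pos < 0:
                raise InputError(f"negative map position for {marker}: {pos}")
            if marker in seen:
                raise InputError(f"duplicate marker name: {marker}")
            seen[marker] = (str(chrom), float(pos))
            by_chrom.setdefault(str(chrom), []).append(float(pos))
        for chrom, positions in by_chrom.items():
            if any(b < a for a, b in zip(positions, positions[1:])):
                raise InputError(f"map positions not sorted on chromosome {chrom}")
        self._index = seen
        self._extents = {
            chrom: (min(p), max(p)) for chrom, p in by_chrom.items()
        }

    def position(self, marker: str) -> tuple[str, float]:
        try:
            return self._index[marker]
        except KeyError:
            raise InputError(f"marker {marker!r} not on the map") from None

    def chromosomes(self) -> list[str]:
        return list(self._extents)

    def extent(self, chrom: str) -> tuple[float, float]:
        try:
            return self._extents[str(chrom)]
        except KeyError:
            raise InputError(f"chromosome {chrom!r} not on the map") from None


@dataclass(frozen=True)
class SubstitutedSegment:
    """Donor segment with certain (core) and recombination-uncertain (maximal) bounds."""

    chromosome: str
    core: Interval
    maximal: Interval

    def __post_init__(self):
        if not self.maximal.contains_interval(self.core):
            raise InputError(
                f"core {self.core} not contained in maximal {self.maximal}"
            )


@dataclass
class SSSLLine:
    line_id: str
    donor_id: str
    segment: SubstitutedSegment | None
    phenotypes: dict[str, list[float]]  # season -> replicate proportions

    def __post_init__(self):
        if not self.phenotypes:
            raise InputError(f"line {self.line_id}: no seasons present")
        for season, reps in self.phenotypes.items():
            for p in reps:
                if not 0.0 <= p <= 1.0:
                    raise InputError(
                        f"line {self.line_id} season {season}: proportion {p} outside [0, 1]"
                    )


@dataclass
class SeasonStats:
    p_value: float
    a: float
    r2: float


@dataclass
class DetectionResult:
    """Per-line QTL call with season-averaged effect summaries.

    ``a_sd``/``r2_sd`` are sample standard deviations (n-1) over the detected
    seasons; for a single detected season they are 0.
    """

    line_id: str
    per_season: dict[str, SeasonStats] = field(default_factory=dict)
    detected_seasons: frozenset[str] = frozenset()
    detected: bool = False
    a_mean: float = math.nan
    a_sd: float = math.nan
    r2_mean: float = math.nan
    r2_sd: float = math.nan
    sign: int = 0
    sign_consistent: bool = True
    donor_id: str = ""

    def validate_threshold(self, alpha: float) -> None:
        bad = [
            s
            for s in self.detected_seasons
            if s in self.per_season and not self.per_season[s].p_value < alpha
        ]
        if bad:
            raise InputError(f"detected seasons {bad} fail p < {alpha}")


@dataclass
class HeritabilityResult:
    per_season: dict[str, float]
    combined: float
    genetic_variance: float
    residual_variance: float

    def __post_init__(self):
        for label, h2 in {**self.per_season, "combined": self.combined}.items():
            if not 0.0 <= h2 <= 1.0:
                raise InputError(f"H2 for {label} outside [0, 1]: {h2}")


# ---------------------------------------------------------------------------
# operations


def arcsine_transform(p):
    """Variance-stabilizing arcsin(sqrt(p)), in radians.

    Accepts a scalar or array-like of proportions in [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise DomainError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def estimate_effect(line_mean: float, parent_mean: float) -> tuple[float, float]:
    """Additive effect and its contribution, on the raw proportion scale.

    a = (line - parent) / 2; R^2 = a / parent (sign carried).
    """
    if parent_mean == 0:
        raise UndefinedStatisticError("parent mean is 0; contribution undefined")
    if parent_mean < 0:
        raise InputError("parent mean must be positive")
    a = (line_mean - parent_mean) / 2.0
    return a, a / parent_mean


def _sample_sd(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def detect_line_qtl(
    line: SSSLLine,
    parent: dict[str, list[float]],
    alpha: float = 0.001,
    min_seasons: int = 2,
    transform: bool = True,
) -> DetectionResult:
    """Two-sample test of a line against the recurrent parent, per season.

    The line is flagged as carrying a putative QTL iff the pooled-variance
    two-sided t-test on (optionally transformed) replicates gives p < ``alpha``
    in at least ``min_seasons`` seasons.  Effect summaries are averaged over
    the detected seasons (over all tested seasons when nothing is detected).
    """
    shared = [s for s in line.phenotypes if s in parent]
    if not shared:
        raise InputError(f"line {line.line_id}: no seasons shared with the parent")

    per_season: dict[str, SeasonStats] = {}
    for season in shared:
        line_reps = np.asarray(line.phenotypes[season], dtype=float)
        par_reps = np.asarray(parent[season], dtype=float)
        if len(line_reps) < 2 or len(par_reps) < 2:
            logger.warning(
                "line %s season %s skipped: fewer than 2 replicates",
                line.line_id,
                season,
            )
            continue
        if transform:
            t_line, t_par = arcsine_transform(line_reps), arcsine_transform(par_reps)
        else:
            t_line, t_par = line_reps, par_reps
        res = stats.ttest_ind(t_line, t_par, equal_var=True)
        a, r2 = estimate_effect(float(line_reps.mean()), float(par_reps.mean()))
        per_season[season] = SeasonStats(float(res.pvalue), a, r2)

    if len(per_season) < min_seasons:
        raise InputError(
            f"line {line.line_id}: only {len(per_season)} usable seasons "
            f"(need {min_seasons})"
        )

    detected_seasons = frozenset(
        s for s, st in per_season.items() if st.p_value < alpha
    )
    detected = len(detected_seasons) >= min_seasons
    basis = sorted(detected_seasons) if detected else sorted(per_season)
    a_vals = [per_season[s].a for s in basis]
    r2_vals = [per_season[s].r2 for s in basis]
    signs = {int(np.sign(per_season[s].a)) for s in (basis if detected else [])}
    a_mean = float(np.mean(a_vals))

    return DetectionResult(
        line_id=line.line_id,
        per_season=per_season,
        detected_seasons=detected_seasons if detected else frozenset(),
        detected=detected,
        a_mean=a_mean,
        a_sd=_sample_sd(a_vals),
        r2_mean=float(np.mean(r2_vals)),
        r2_sd=_sample_sd(r2_vals),
        sign=int(np.sign(a_mean)),
        sign_consistent=len(signs) <= 1,
        donor_id=line.donor_id,
    )


def _oneway_components(groups: list[np.ndarray]) -> tuple[float, float]:
    """Method-of-moments variance components (sigma2_between, sigma2_within)
    from a one-way random-effects layout, unbalanced-n0 correction."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (k - 1)
    df_within = N - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (ns**2).sum() / N) / (k - 1)
    sigma_g = max(0.0, (ms_between - ms_within) / n0)
    return sigma_g, ms_within


def estimate_H2(
    lines: dict[str, dict[str, list[float]]],
    seasons: list[str] | None = None,
) -> HeritabilityResult:
    """Broad-sense heritability from replicate proportions per line and season.

    Per season: one-way random-effects partition over lines,
    H2 = sigma2_G / (sigma2_G + sigma2_e), negative estimates truncated at 0.
    Combined: season means are removed (season as a fixed stratum) and the
    same one-way partition is applied to the pooled centred replicates.
    """
    if len(lines) < 2:
        raise InputError("need at least 2 lines")
    if seasons is None:
        seasons = sorted({s for v in lines.values() for s in v})

    per_season: dict[str, float] = {}
    combined_groups: dict[str, list[np.ndarray]] = {lid: [] for lid in lines}
    for season in seasons:
        groups = []
        for lid, by_season in lines.items():
            reps = np.asarray(by_season.get(season, []), dtype=float)
            if len(reps) >= 2:
                groups.append(reps)
        if len(groups) < 2:
            continue
        sg, se = _oneway_components(groups)
        per_season[season] = sg / (sg + se) if (sg + se) > 0 else 0.0
        season_mean = np.concatenate(groups).mean()
        for lid, by_season in lines.items():
            reps = np.asarray(by_season.get(season, []), dtype=float)
            if len(reps) >= 2:
                combined_groups[lid].append(reps - season_mean)

    pooled = [np.concatenate(g) for g in combined_groups.values() if g]
    if len(pooled) < 2:
        raise InputError("fewer than 2 lines with >=2 replicates in any season")
    sg, se = _oneway_components(pooled)
    combined = sg / (sg + se) if (sg + se) > 0 else 0.0
    return HeritabilityResult(
        per_season=per_season,
        combined=combined,
        genetic_variance=sg,
        residual_variance=se,
    )


def anova_blocks(
    blocks: list[list[float]], transform: bool = True
) -> tuple[float, float]:
    """One-way ANOVA across replicate blocks (environment-consistency check)."""
    if len(blocks) < 2:
        raise InputError("need at least 2 blocks")
    arrays = []
    for i, b in enumerate(blocks):
        if len(b) < 2:
            raise InputError(f"block {i} has fewer than 2 values")
        arr = np.asarray(b, dtype=float)
        arrays.append(arcsine_transform(arr) if transform else arr)
    allv = np.concatenate(arrays)
    if np.allclose(allv, allv[0]):
        raise DegenerateInputError("zero total variance across blocks")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
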