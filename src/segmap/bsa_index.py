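"""Two-bulk allele-depth index scans with simulated null confidence bands.

Per site, each bulk's index is the fraction of reads carrying the donor
allele, and the delta index is (tolerant bulk - sensitive bulk).  Tracks are
smoothed with a sliding-window mean; null bands come from Monte-Carlo
simulation of unlinked sites: bulk allele frequency ~ Binomial(2*pool_size,
1/2) / (2*pool_size) and read counts ~ Binomial(depth, frequency), averaged
over the sites of each window exactly as the data track is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "PooledVariantSite",
    "DeltaTrack",
    "CandidateInterval",
    "snp_index",
    "delta_index",
    "filter_sites",
    "smooth_track",
    "null_band",
    "attach_bands",
    "call_intervals",
]


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """Donor-allele read fraction; NaN when total depth is 0 (site excluded)."""
    if ref_depth < 0 or alt_depth < 0:
        raise InputError("depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        return math.nan
    return alt_depth / total


def delta_index(index_tolerant: float, index_sensitive: float) -> float:
    for v in (index_tolerant, index_sensitive):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"index {v} outside [0, 1]")
    return index_tolerant - index_sensitive


@dataclass
class PooledVariantSite:
    chromosome: str
    position: int
    ref: str
    alt: str
    ref_hi: int  # tolerant bulk
    alt_hi: int
    ref_lo: int  # sensitive bulk
    alt_lo: int
    variant_class: str = "SNP"  # "SNP" or "InDel"

    def __post_init__(self):
        if min(self.ref_hi, self.alt_hi, self.ref_lo, self.alt_lo) < 0:
            raise InputError("depths must be non-negative")

    @property
    def index_hi(self) -> float:
        return snp_index(self.ref_hi, self.alt_hi)

    @property
    def index_lo(self) -> float:
        return snp_index(self.ref_lo, self.alt_lo)

    @property
    def delta(self) -> float:
        hi, lo = self.index_hi, self.index_lo
        if math.isnan(hi) or math.isnan(lo):
            return math.nan
        return delta_index(hi, lo)

    @property
    def depth_hi(self) -> int:
        return self.ref_hi + self.alt_hi

    @property
    def depth_lo(self) -> int:
        return self.ref_lo + self.alt_lo


@dataclass
class DeltaTrack:
    chromosome: str
    centers: np.ndarray  # window centers, bp
    values: np.ndarray  # smoothed delta, NaN for empty windows
    window: float
    step: float
    n_sites: np.ndarray
    # per-window member-site depths, needed to simulate matched null bands
    site_depths_hi: list[np.ndarray] = field(default_factory=list)
    site_depths_lo: list[np.ndarray] = field(default_factory=list)
    bands: dict[float, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for lower, upper in self.bands.values():
            if np.any(lower > upper):
                raise InputError("band lower bound exceeds upper bound")


@dataclass
class CandidateInterval:
    chromosome: str
    start: float
    end: float
    peak_delta: float
    level: float

    def __post_init__(self):
        if self.end < self.start:
            raise InputError("interval start > end")


def filter_sites(
    sites: list[PooledVariantSite],
    min_depth: int = 10,
    min_index_either: float = 0.3,
) -> list[PooledVariantSite]:
    """Default site filters: minimum per-pool depth; drop sites whose index is
    below ``min_index_either`` in both pools (likely alignment artefacts)."""
    kept = []
    for s in sites:
        if s.depth_hi < min_depth or s.depth_lo < min_depth:
            continue
        if s.index_hi < min_index_either and s.index_lo < min_index_either:
            continue
        kept.append(s)
    return kept


def _window_starts(lo: float, hi: float, window: float, step: float) -> np.ndarray:
    n = max(1, int(math.floor((hi - lo) / step)) + 1)
    return lo + step * np.arange(n)


def smooth_track(
    sites: list[PooledVariantSite], window: float, step: float
) -> DeltaTrack:
    """Sliding-window arithmetic mean of per-site delta along one chromosome."""
    if not (step > 0 and window >= step):
        raise InputError("require window >= step > 0")
    if not sites:
        raise InputError("no sites")
    chroms = {s.chromosome for s in sites}
    if len(chroms) > 1:
        raise InputError("smooth_track operates on a single chromosome")
    pos = np.array([s.position for s in sites], dtype=float)
    if np.any(np.diff(pos) < 0):
        raise InputError("sites must be sorted by position")
    deltas = np.array([s.delta for s in sites], dtype=float)
    d_hi = np.array([s.depth_hi for s in sites], dtype=float)
    d_lo = np.array([s.depth_lo for s in sites], dtype=float)
    usable = ~np.isnan(deltas)

    starts = _window_starts(pos[0], pos[-1], window, step)
    centers, values, n_sites = [], [], []
    depths_hi, depths_lo = [], []
    for w in starts:
        in_win = (pos >= w) & (pos < w + window) & usable
        centers.append(w + window / 2.0)
        n = int(in_win.sum())
        n_sites.append(n)
        values.append(float(deltas[in_win].mean()) if n else math.nan)
        depths_hi.append(d_hi[in_win])
        depths_lo.append(d_lo[in_win])
    return DeltaTrack(
        chromosome=sites[0].chromosome,
        centers=np.array(centers),
        values=np.array(values),
        window=float(window),
        step=float(step),
        n_sites=np.array(n_sites),
        site_depths_hi=depths_hi,
        site_depths_lo=depths_lo,
    )


def _simulate_window_deltas(
    rng: np.random.Generator,
    depths_hi: np.ndarray,
    depths_lo: np.ndarray,
    pool_size: int,
    n_sim: int,
) -> np.ndarray:
    """Null window-mean deltas, shape (n_sim,)."""
    m = len(depths_hi)
    if m == 0:
        return np.full(n_sim, np.nan)
    chroms = 2 * pool_size

    def pool_index(depths: np.ndarray) -> np.ndarray:
        freq = rng.binomial(chroms, 0.5, size=(n_sim, m)) / chroms
        d = np.broadcast_to(depths, (n_sim, m)).astype(int)
        alt = rng.binomial(d, freq)
        return np.where(d > 0, alt / np.maximum(d, 1), np.nan)

    deltas = pool_index(depths_hi) - pool_index(depths_lo)
    with np.errstate(invalid="ignore"):
        return np.nanmean(deltas, axis=1)


def null_band(
    window_depths: list[tuple[np.ndarray, np.ndarray]],
    pool_size: int,
    n_sim: int = 10_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed: int | None = None,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Monte-Carlo two-sided null quantile bands, one pair of arrays per level.

    ``window_depths`` gives, per window, the member sites' read depths in the
    tolerant and sensitive bulks.
    """
    if pool_size <= 0:
        raise InputError("pool_size must be positive")
    if n_sim < 1000:
        raise InputError("n_sim must be at least 1000")
    for level in levels:
        if n_sim * (1.0 - level) < 2:
            raise InputError(f"n_sim={n_sim} too small for level {level}")
    rng = np.random.default_rng(seed)
    n_win = len(window_depths)
    bands = {
        level: (np.full(n_win, np.nan), np.full(n_win, np.nan)) for level in levels
    }
    for i, (dh, dl) in enumerate(window_depths):
        sims = _simulate_window_deltas(rng, np.asarray(dh), np.asarray(dl), pool_size, n_sim)
        if np.all(np.isnan(sims)):
            continue
        for level in levels:
            tail = (1.0 - level) / 2.0
            lo, hi = np.nanquantile(sims, [tail, 1.0 - tail])
            bands[level][0][i] = lo
            bands[level][1][i] = hi
    return bands


def attach_bands(
    track: DeltaTrack,
    pool_size: int,
    n_sim: int = 10_000,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed: int | None = None,
) -> DeltaTrack:
    """Compute null bands matched to the track's window depth profile."""
    depths = list(zip(track.site_depths_hi, track.site_depths_lo))
    track.bands = null_band(depths, pool_size, n_sim=n_sim, levels=levels, seed=seed)
    return track


def call_intervals(track: DeltaTrack, level: float) -> list[CandidateInterval]:
    """Maximal runs of consecutive windows whose smoothed delta exceeds the
    band on either side; runs separated by less than one step are merged."""
    if level not in track.bands:
        raise InputError(f"track has no band at level {level}")
    lower, upper = track.bands[level]
    with np.errstate(invalid="ignore"):
        exceed = (track.values > upper) | (track.values < lower)
    idx = np.flatnonzero(exceed & ~np.isnan(track.values))
    if idx.size == 0:
        return []
    # windows are on a regular center grid; consecutive == center gap <= step
    gap_tol = track.step * 1.5
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if track.centers[i] - track.centers[runs[-1][-1]] <= gap_tol:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    out = []
    half = track.window / 2.0
    for run in runs:
        vals = track.values[run]
        peak = vals[np.argmax(np.abs(vals))]
        out.append(
            CandidateInterval(
                chromosome=track.chromosome,
                start=float(track.centers[run[0]] - half),
                end=float(track.centers[run[-1]] + half),
                peak_delta=float(peak),
                level=level,
            )
        )
    return out
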