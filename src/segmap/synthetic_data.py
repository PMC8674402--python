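"""Forward simulators with known ground truth for every pipeline stage.

All generators are pure functions of (config, seed): substitution-line
libraries with planted additive effects and binomial germination counts,
F2 populations via Haldane (no-interference) recombination, and pooled-bulk
read depths for the two phenotypic-extreme bulks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .f2_genetics import F2Individual
from .bsa_index import PooledVariantSite
from .intervals import Interval
from .sssl_core import GeneticMap, SSSLLine, SubstitutedSegment

__all__ = [
    "ChromosomeSpec",
    "PlantedQTL",
    "SimConfig",
    "simulate_sssl_library",
    "simulate_f2",
    "simulate_pools",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_cM: float
    length_bp: int
    n_markers: int


@dataclass(frozen=True)
class PlantedQTL:
    chromosome: str
    pos_cM: float
    a: float  # additive effect, proportion units
    d: float = 0.0  # dominance deviation
    pos_bp: int | None = None


@dataclass
class SimConfig:
    chromosomes: list[ChromosomeSpec] = field(
        default_factory=lambda: [
            ChromosomeSpec("1", 150.0, 40_000_000, 16),
            ChromosomeSpec("2", 120.0, 32_000_000, 13),
        ]
    )
    qtls: list[PlantedQTL] = field(default_factory=list)
    season_baselines: dict[str, float] = field(
        default_factory=lambda: {"a": 0.68, "b": 0.57, "c": 0.55, "d": 0.44}
    )
    season_shift_sd: float = 0.0  # extra line-by-season noise on the mean
    residual_sd: float = 0.03  # within-line replicate-level noise on the mean
    seeds_per_replicate: int = 150
    replicates: int = 5
    segment_length_range: tuple[float, float] = (5.0, 40.0)
    pool_size: int = 30
    mean_depth: float = 30.0
    clip: tuple[float, float] = (0.01, 0.99)

    def __post_init__(self):
        if self.residual_sd < 0 or self.season_shift_sd < 0:
            raise InputError("variance parameters must be non-negative")
        if self.seeds_per_replicate <= 0 or self.replicates <= 0:
            raise InputError("seeds_per_replicate and replicates must be positive")
        if self.pool_size <= 0:
            raise InputError("pool_size must be positive")
        if self.mean_depth < 0:
            raise InputError("mean_depth must be non-negative")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names")
        for q in self.qtls:
            if q.chromosome not in names:
                raise InputError(f"planted QTL on unknown chromosome {q.chromosome}")


def _haldane_r(d_cM: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _uniform_marker_map(config: SimConfig) -> GeneticMap:
    entries = []
    for spec in config.chromosomes:
        positions = np.linspace(0.0, spec.length_cM, spec.n_markers)
        for i, pos in enumerate(positions):
            entries.append((f"M{spec.name}_{i:03d}", spec.name, float(pos)))
    return GeneticMap(entries)


def _sample_proportion(
    rng: np.random.Generator, mean: float, config: SimConfig, size: int
) -> np.ndarray:
    lo, hi = config.clip
    p_rep = np.clip(
        mean + rng.normal(0.0, config.residual_sd, size=size), lo, hi
    )
    n = config.seeds_per_replicate
    return rng.binomial(n, p_rep) / n


def simulate_sssl_library(
    config: SimConfig, n_lines: int, seed: int | None = None
) -> tuple[GeneticMap, list[SSSLLine], pd.DataFrame]:
    """Library of single-segment lines with season-structured phenotypes.

    Each line receives one uniform-random segment; carriers of a planted QTL
    shift their seasonal mean by 2a (homozygous substitution).  Returns the
    marker map, the lines (the recurrent parent is emitted as line 'P0' with
    no segment), and a truth table of carried QTLs.
    """
    if n_lines < 1:
        raise InputError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    gmap = _uniform_marker_map(config)
    seasons = list(config.season_baselines)

    parent = SSSLLine(
        line_id="P0",
        donor_id="",
        segment=None,
        phenotypes={
            s: list(_sample_proportion(rng, config.season_baselines[s], config, config.replicates))
            for s in seasons
        },
    )

    lines = [parent]
    truth_rows = []
    lmin, lmax = config.segment_length_range
    for i in range(n_lines):
        spec = config.chromosomes[rng.integers(len(config.chromosomes))]
        seg_len = min(float(rng.uniform(lmin, lmax)), spec.length_cM)
        start = float(rng.uniform(0.0, spec.length_cM - seg_len))
        core = Interval(start, start + seg_len)
        segment = SubstitutedSegment(spec.name, core, core)
        carried = [
            q
            for q in config.qtls
            if q.chromosome == spec.name and core.contains(q.pos_cM)
        ]
        shift = sum(2.0 * q.a for q in carried)
        phenos = {}
        for s in seasons:
            mean = (
                config.season_baselines[s]
                + shift
                + (rng.normal(0.0, config.season_shift_sd) if config.season_shift_sd else 0.0)
            )
            phenos[s] = list(
                _sample_proportion(rng, mean, config, config.replicates)
            )
        line_id = f"L{i + 1:04d}"
        lines.append(SSSLLine(line_id, "D1", segment, phenos))
        for q in carried:
            truth_rows.append(
                {"line_id": line_id, "chromosome": q.chromosome, "pos_cM": q.pos_cM, "a": q.a}
            )
    truth = pd.DataFrame(truth_rows, columns=["line_id", "chromosome", "pos_cM", "a"])
    return gmap, lines, truth


def _simulate_gametes(
    rng: np.random.Generator, marker_cM: np.ndarray, n: int
) -> np.ndarray:
    """n gametes over ordered marker positions; 1 = donor allele."""
    m = len(marker_cM)
    alleles = np.empty((n, m), dtype=int)
    alleles[:, 0] = rng.random(n) < 0.5
    for j in range(1, m):
        r = _haldane_r(marker_cM[j] - marker_cM[j - 1])
        swap = rng.random(n) < r
        alleles[:, j] = np.where(swap, 1 - alleles[:, j - 1], alleles[:, j - 1])
    return alleles


def simulate_f2(
    config: SimConfig,
    n_individuals: int,
    marker_cM: list[float] | None = None,
    causal_index: int | None = None,
    a: float = 0.0,
    d: float = 0.0,
    mu: float = 0.5,
    seed: int | None = None,
) -> tuple[list[F2Individual], list[str]]:
    """F2 population from a self of a heterozygous segment.

    Markers sit at ``marker_cM`` positions (default: 11 markers over 50 cM);
    ``causal_index`` points at the marker carrying the phenotype effect.
    Phenotype = mu + a*x + d*z + noise, then binomial germination sampling.
    """
    if n_individuals < 1:
        raise InputError("n_individuals must be >= 1")
    if marker_cM is None:
        marker_cM = list(np.linspace(0.0, 50.0, 11))
    pos = np.asarray(marker_cM, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise InputError("marker positions must be sorted")
    rng = np.random.default_rng(seed)
    gam1 = _simulate_gametes(rng, pos, n_individuals)
    gam2 = _simulate_gametes(rng, pos, n_individuals)
    dosage = gam1 + gam2  # 0/1/2 donor alleles
    codes = dosage + 1  # 1/2/3

    names = [f"M{j:03d}" for j in range(len(pos))]
    if causal_index is None:
        causal_index = len(pos) // 2
    x = dosage[:, causal_index] - 1.0
    z = (dosage[:, causal_index] == 1).astype(float)
    lo, hi = config.clip
    mean = np.clip(
        mu + a * x + d * z + rng.normal(0.0, config.residual_sd, n_individuals),
        lo,
        hi,
    )
    pheno = rng.binomial(config.seeds_per_replicate, mean) / config.seeds_per_replicate

    individuals = [
        F2Individual(
            individual_id=f"F{i + 1:04d}",
            genotypes={names[j]: int(codes[i, j]) for j in range(len(pos))},
            phenotype=float(pheno[i]),
        )
        for i in range(n_individuals)
    ]
    return individuals, names


def simulate_pools(
    individuals: list[F2Individual],
    markers: list[str],
    chromosome: str = "1",
    positions_bp: list[int] | None = None,
    depth: float = 30.0,
    pool_size: int = 30,
    seed: int | None = None,
) -> list[PooledVariantSite]:
    """Pooled read depths for the two phenotypic-extreme bulks of an F2.

    Bulk membership is by phenotype rank (ties broken by individual id); per
    site the bulk allele frequency is the mean donor dosage / 2 over bulk
    members, read depth ~ Poisson(depth), donor reads ~ Binomial(depth, f).
    Zero-depth draws yield sites that are missing in that pool.
    """
    if len(individuals) < 2 * pool_size:
        raise InputError(
            f"population of {len(individuals)} cannot fill two bulks of {pool_size}"
        )
    if positions_bp is None:
        positions_bp = [int(1_000_000 * (j + 1)) for j in range(len(markers))]
    if len(positions_bp) != len(markers):
        raise InputError("positions_bp must match markers")
    rng = np.random.default_rng(seed)
    ranked = sorted(
        individuals, key=lambda ind: (ind.phenotype, ind.individual_id)
    )
    lo_bulk, hi_bulk = ranked[:pool_size], ranked[-pool_size:]

    sites = []
    for marker, pos in zip(markers, positions_bp):
        site_depths = rng.poisson(depth, size=2)
        freqs = []
        for bulk in (hi_bulk, lo_bulk):
            dosage = np.array([ind.genotypes[marker] - 1 for ind in bulk], dtype=float)
            freqs.append(dosage.mean() / 2.0)
        alt_hi = int(rng.binomial(site_depths[0], freqs[0]))
        alt_lo = int(rng.binomial(site_depths[1], freqs[1]))
        sites.append(
            PooledVariantSite(
                chromosome=chromosome,
                position=pos,
                ref="A",
                alt="T",
                ref_hi=int(site_depths[0]) - alt_hi,
                alt_hi=alt_hi,
                ref_lo=int(site_depths[1]) - alt_lo,
                alt_lo=alt_lo,
            )
        )
    return sites
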