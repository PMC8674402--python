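"""F2 segregation tests, coded single-marker regression, and fine mapping.

Genotypes are coded 1/2/3 (recipient homozygote, heterozygote, donor
homozygote).  The additive/dominance regression uses x in {-1, 0, +1} and
z in {0, 1, 0}; with balanced groups a = (mean3 - mean1)/2 and
d = mean2 - (mean1 + mean3)/2.  Fine mapping reuses the closed-interval
engine on physical (1-based, closed) bp intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InputError, UndefinedStatisticError
from .intervals import Interval, localize

logger = logging.getLogger(__name__)

__all__ = [
    "F2Individual",
    "Model1Fit",
    "RecombinantPopulation",
    "segregation_chi2",
    "fit_model1",
    "marker_trait_association",
    "fine_map",
    "bp_length",
]

VALID_CODES = {1, 2, 3}


def bp_length(interval: Interval) -> int:
    """Length of a 1-based closed physical interval, in bp."""
    return int(interval.end - interval.start + 1)


@dataclass
class F2Individual:
    individual_id: str
    genotypes: dict[str, int | None]
    phenotype: float | None = None

    def __post_init__(self):
        for marker, code in self.genotypes.items():
            if code is not None and code not in VALID_CODES:
                raise InputError(
                    f"{self.individual_id}: genotype code {code!r} at {marker} "
                    "not in {1, 2, 3}"
                )


@dataclass
class Model1Fit:
    mu: float
    a: float | None
    d: float | None
    se_a: float | None
    se_d: float | None
    p_a: float | None
    p_d: float | None
    r_squared: float
    residual_variance: float
    n: int
    inestimable: frozenset[str] = frozenset()


@dataclass
class RecombinantPopulation:
    """Progeny of one recombinant plant heterozygous over a physical interval."""

    recomb_id: str
    chromosome: str
    het_interval: Interval
    marker_id: str
    marker_pos: float | None = None
    progeny: list[F2Individual] = field(default_factory=list)
    r: float | None = None
    p: float | None = None

    def __post_init__(self):
        if self.marker_pos is not None and not self.het_interval.contains(
            self.marker_pos
        ):
            raise InputError(
                f"{self.recomb_id}: marker {self.marker_id} at {self.marker_pos} "
                f"outside heterozygous interval {self.het_interval}"
            )

    def association(self) -> tuple[float, float]:
        """Marker-trait (r, p): cached values if present, else computed."""
        if self.r is not None and self.p is not None:
            return self.r, self.p
        if not self.progeny:
            raise InputError(f"{self.recomb_id}: no progeny and no cached association")
        self.r, self.p = marker_trait_association(self.progeny, self.marker_id)
        return self.r, self.p


def segregation_chi2(
    counts: list[int], ratio: list[float]
) -> tuple[float, int, float]:
    """Pearson chi-square of genotype class counts against expected proportions.

    No continuity correction; df = number of classes - 1.
    """
    obs = np.asarray(counts, dtype=float)
    props = np.asarray(ratio, dtype=float)
    if obs.shape != props.shape:
        raise InputError("counts and ratio must have equal length")
    if np.any(obs < 0):
        raise InputError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise InputError("total count must be positive")
    if not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise InputError("expected proportions must sum to 1")
    expected = total * props
    if np.any(expected == 0):
        raise InputError("expected count of 0 in some class")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _complete_cases(
    individuals: list[F2Individual], marker: str
) -> tuple[np.ndarray, np.ndarray]:
    codes, phenos, dropped = [], [], 0
    for ind in individuals:
        code = ind.genotypes.get(marker)
        if code is None or ind.phenotype is None:
            dropped += 1
            continue
        codes.append(code)
        phenos.append(ind.phenotype)
    if dropped:
        logger.info("%d individuals dropped for missing data at %s", dropped, marker)
    return np.asarray(codes, dtype=int), np.asarray(phenos, dtype=float)


def fit_model1(individuals: list[F2Individual], marker: str) -> Model1Fit:
    """OLS fit of y = mu + a*x + d*z with the 1/2/3 dummy coding.

    With only two genotype classes present the missing contrast is flagged in
    ``inestimable`` and the reduced model y = mu + a*x is fitted.
    """
    codes, y = _complete_cases(individuals, marker)
    classes = set(codes.tolist())
    if len(classes) < 2:
        raise InputError("only one genotype class present: singular design")

    x = np.where(codes == 1, -1.0, np.where(codes == 3, 1.0, 0.0))
    z = np.where(codes == 2, 1.0, 0.0)

    inestimable: set[str] = set()
    if classes == {1, 3}:
        inestimable.add("d")  # no heterozygotes: dominance not observable
    elif len(classes) == 2:
        inestimable.add("d")  # x and z collinear: a and d confounded
        inestimable.add("a_confounded_with_d")

    if "d" in inestimable:
        X = sm.add_constant(x)
    else:
        X = sm.add_constant(np.column_stack([x, z]))
    fit = sm.OLS(y, X).fit()

    params = fit.params
    mu = float(params[0])
    a = float(params[1])
    se = fit.bse
    pv = fit.pvalues
    if "d" in inestimable:
        d = se_d = p_d = None
    else:
        d, se_d, p_d = float(params[2]), float(se[2]), float(pv[2])
    return Model1Fit(
        mu=mu,
        a=a,
        d=d,
        se_a=float(se[1]),
        se_d=se_d,
        p_a=float(pv[1]),
        p_d=p_d,
        r_squared=float(fit.rsquared) if y.var() > 0 else 0.0,
        residual_variance=float(fit.mse_resid),
        n=len(y),
        inestimable=frozenset(inestimable),
    )


def marker_trait_association(
    progeny: list[F2Individual], marker: str
) -> tuple[float, float]:
    """Pearson correlation between genotype code and phenotype, two-sided p."""
    codes, y = _complete_cases(progeny, marker)
    if len(codes) < 3:
        raise InputError("need at least 3 complete cases")
    if np.var(codes) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = stats.pearsonr(codes.astype(float), y)
    return float(res.statistic), float(res.pvalue)


def fine_map(
    populations: list[RecombinantPopulation], alpha: float = 0.01
) -> list[Interval]:
    """Physical localization from recombinant-progeny association tests.

    Interval = intersection of heterozygous intervals of populations with
    p < alpha, minus the interiors of heterozygous intervals of populations
    with p >= alpha.
    """
    if not populations:
        raise InputError("need at least one recombinant population")
    chroms = {p.chromosome for p in populations}
    if len(chroms) > 1:
        raise InputError(f"populations span multiple chromosomes: {sorted(chroms)}")
    significant, nonsignificant = [], []
    for pop in populations:
        _, p = pop.association()
        (significant if p < alpha else nonsignificant).append(pop)
    if not significant:
        raise InputError("no population significant at the requested level")
    return localize(
        [p.het_interval for p in significant],
        [p.het_interval for p in nonsignificant],
        member_ids=[p.recomb_id for p in significant],
    )
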