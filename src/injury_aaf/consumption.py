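"""Average daily alcohol consumption: survey triangulation and gamma modelling.

Population surveys systematically underestimate consumption relative to
adult per-capita figures derived from sales, import and export data
(the most accurate population-level measure).  Survey group means are
therefore up-shifted by a single coverage factor:

    coverage  = (population-weighted survey mean) / ((1 - spillage) * per_capita)
    corrected = raw_mean / coverage

where ``spillage`` (default 10%) is the fraction of recorded per-capita
consumption assumed never actually drunk (waste, stockpiling).

Among current drinkers, daily intake x (g/day) is modelled as a gamma
distribution whose standard deviation is an empirical function of the
mean (a linear regression through the origin with per-sex coefficients);
shape and scale then follow by moment matching.  Lifetime abstainers and
former drinkers carry a point mass at zero handled by the AAF engine,
not by the gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConsumptionSummary",
    "GammaConsumption",
    "PointMassConsumption",
    "coverage_upshift",
    "sd_from_mean",
    "fit_gamma",
    "gamma_density",
    "DEFAULT_SD_COEFFICIENTS",
    "DEFAULT_SPILLAGE",
]

#: Per-sex slope of the sd(mean) regression through the origin
#: (empirical values from the gamma-modelling literature; configuration,
#: not a law — any monotone sd function can be substituted).
DEFAULT_SD_COEFFICIENTS: Mapping[str, float] = {"M": 1.171, "W": 1.258}

#: Fraction of recorded adult per-capita consumption assumed not consumed.
DEFAULT_SPILLAGE = 0.10


@dataclass
class ConsumptionSummary:
    """One age x sex stratum of survey consumption estimates.

    ``p_abstainer_former + p_current`` must equal 1; binge drinkers are a
    subset of current drinkers, so ``binge_prevalence <= p_current``.
    ``binge_dose`` (g/occasion) is optional: when absent the scenario's
    drinks-per-occasion rule supplies it.  ``population`` is a relative
    stratum weight used to form the survey-implied population mean.
    """

    age_group: str
    sex: str  # "M" or "W"
    p_abstainer_former: float
    p_current: float
    raw_mean: float  # g/day among current drinkers
    raw_mean_se: float = float("nan")
    binge_prevalence: float = 0.0  # proportion of the whole population
    binge_occasions_per_year: float = 0.0
    binge_dose: Optional[float] = None  # g/occasion (per-group rule, e.g. SA III)
    population: float = 1.0
    corrected_mean: Optional[float] = None  # filled by coverage_upshift
    gamma_shape: Optional[float] = None  # override of the fitted shape (MC draws)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "W"):
            raise ValueError(f"sex must be 'M' or 'W', got {self.sex!r}")
        for name in ("p_abstainer_former", "p_current", "binge_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.p_abstainer_former + self.p_current - 1.0) > 1e-9:
            raise ValueError(
                "p_abstainer_former + p_current must equal 1 "
                f"(got {self.p_abstainer_former + self.p_current})"
            )
        if self.binge_prevalence > self.p_current + 1e-9:
            raise ValueError("binge drinkers must be a subset of current drinkers")
        if self.raw_mean < 0:
            raise ValueError("raw_mean must be non-negative")
        if not 0.0 <= self.binge_occasions_per_year <= 365.0:
            raise ValueError("binge_occasions_per_year must lie in [0, 365]")
        if self.population <= 0:
            raise ValueError("population weight must be positive")

    @property
    def group(self) -> Tuple[str, str]:
        return (self.age_group, self.sex)

    @property
    def p_current_nonbinge(self) -> float:
        return self.p_current - self.binge_prevalence

    @property
    def mean_for_risk(self) -> float:
        """Corrected mean if the up-shift has been applied, else the raw mean."""
        return self.raw_mean if self.corrected_mean is None else self.corrected_mean


@dataclass(frozen=True)
class GammaConsumption:
    """Gamma distribution of daily intake among current drinkers.

    ``shape * scale`` equals the mean by construction.  (Beware that some
    of the epidemiological literature swaps the labels of the two
    parameters; here ``shape`` and ``scale`` follow the standard
    convention, i.e. scipy's ``a`` and ``scale``.)
    """

    shape: float  # dimensionless
    scale: float  # g/day

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale

    def pdf(self, x):
        return gamma_density(self, x)


@dataclass(frozen=True)
class PointMassConsumption:
    """Degenerate intake distribution: every drinker consumes ``at`` g/day.

    The limit of a gamma as sd -> 0; used for closed-form validation and
    for sensitivity runs that collapse the distribution onto the mean.
    """

    at: float  # g/day

    def __post_init__(self) -> None:
        if self.at < 0:
            raise ValueError("point mass location must be non-negative")

    @property
    def mean(self) -> float:
        return self.at


def coverage_upshift(
    summaries: Iterable[ConsumptionSummary],
    per_capita: float,
    spillage_fraction: float = DEFAULT_SPILLAGE,
) -> Tuple[float, List[ConsumptionSummary]]:
    """Up-shift survey means to match (1 - spillage) of adult per-capita consumption.

    The survey-implied population mean is the population-weighted average
    of ``p_current * raw_mean`` over strata (abstainers contribute zero).
    A single coverage factor is computed for the whole population and its
    inverse applied uniformly to every stratum mean.

    Returns ``(upshift_factor, corrected_summaries)`` where
    ``upshift_factor = 1 / coverage`` and each returned summary has
    ``corrected_mean = raw_mean * upshift_factor``.
    """
    groups = list(summaries)
    if not groups:
        raise ValueError("no consumption summaries supplied")
    if per_capita <= 0:
        raise ValueError("per_capita must be positive (g/day)")
    if not 0.0 <= spillage_fraction < 1.0:
        raise ValueError("spillage_fraction must lie in [0, 1)")
    weights = np.array([g.population for g in groups], dtype=float)
    drinker_means = np.array([g.p_current * g.raw_mean for g in groups], dtype=float)
    survey_mean = float(weights @ drinker_means / weights.sum())
    if survey_mean <= 0:
        raise ValueError("survey-implied population mean is zero; cannot up-shift")
    coverage = survey_mean / ((1.0 - spillage_fraction) * per_capita)
    factor = 1.0 / coverage
    corrected = [replace(g, corrected_mean=g.raw_mean * factor) for g in groups]
    return factor, corrected


def sd_from_mean(mean: float, coefficient: float) -> float:
    """Standard deviation of daily intake as a linear function of the mean.

    ``sd = coefficient * mean`` (regression through the origin); the
    per-sex coefficients are configuration
    (:data:`DEFAULT_SD_COEFFICIENTS`).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if coefficient <= 0:
        raise ValueError("sd coefficient must be positive")
    return coefficient * mean


def fit_gamma(mean: float, sd: float) -> GammaConsumption:
    """Moment-match a gamma distribution: shape = (mean/sd)^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return GammaConsumption(shape=(mean / sd) ** 2, scale=sd**2 / mean)


def gamma_density(dist: GammaConsumption, x):
    """Gamma density of daily intake; zero for x < 0 by convention."""
    x_arr = np.asarray(x, dtype=float)
    out = np.where(
        x_arr < 0, 0.0, stats.gamma.pdf(np.maximum(x_arr, 0.0), a=dist.shape, scale=dist.scale)
    )
    return float(out) if np.ndim(x) == 0 else out
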