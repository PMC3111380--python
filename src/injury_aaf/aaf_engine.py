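"""Alcohol-attributable fractions for injury mortality.

The attributable fraction is computed separately for the two dimensions
of drinking and then combined:

* **Binge component** — a three-category attributable fraction over
  {lifetime abstainers + former drinkers, current non-binge drinkers,
  binge drinkers}, where only the binge group carries excess risk.  The
  crude per-occasion relative risk at the binge dose is down-weighted by
  the proportion of a binge day actually spent at risk and by the
  proportion of days on which binging occurs:

      RR_binge = 1 + (RR_crude(x) - 1) * P_day_at_risk(x) * P_days_at_risk

* **Average-volume component** — a continuous attributable fraction
  integrating the gamma-distributed daily intake of current drinkers
  against the time-at-risk-adjusted relative risk; daily consumption
  occurs every day, so no occasion-frequency factor is applied:

      RR_avg(x) = 1 + (RR_crude(x) - 1) * P_day_at_risk(x)
      A         = P_current * Int pdf(x) * (RR_avg(x) - 1) dx
      AAF_avg   = A / (A + 1)

Both adjusted-RR forms are exposure-time mixtures of at-risk and sober
time: they reduce to 1 as exposure time goes to zero and to the crude RR
as it goes to one.  The two components are added on the AAF scale
(clipped at 1) and multiplied by cause-specific death counts to obtain
attributable deaths.  Alcohol-poisoning causes (X45, X65) are wholly
attributable by definition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import consumption as cons
from . import exposure_time as expo
from .causes import WHOLLY, CauseMap, default_cause_map
from .consumption import ConsumptionSummary, GammaConsumption, PointMassConsumption
from .exposure_time import MetabolismModel
from .risk_model import MVA, NON_MVA, RiskCurve, rr_crude

__all__ = [
    "ScenarioConfig",
    "AAFEstimate",
    "InputBundle",
    "aaf_categorical",
    "rr_binge_adjusted",
    "rr_average_adjusted",
    "aaf_binge",
    "aaf_average",
    "combine_aaf",
    "wholly_attributable",
    "aggregate_aaf",
    "run_scenario",
    "estimates_to_frame",
]

log = logging.getLogger("injury_aaf")

SCENARIOS = ("main", "SA_I", "SA_II", "SA_III")

#: Drinks per occasion by scenario: (men, women).
SCENARIO_BINGE_DRINKS: Mapping[str, Tuple[float, float]] = {
    "main": (5.0, 4.0),
    "SA_I": (6.0, 5.0),
    "SA_II": (7.0, 6.0),
}

IntakeDist = Union[GammaConsumption, PointMassConsumption]


@dataclass(frozen=True)
class ScenarioConfig:
    """All tunable constants of one analysis scenario.

    ``scenario`` selects the binge-dose rule: the main analysis uses
    5 drinks per occasion for men and 4 for women; sensitivity analyses
    I and II raise this to 6/5 and 7/6; sensitivity analysis III takes
    per-group doses from the ``binge_dose`` field of each consumption
    summary (externally estimated group means).
    """

    scenario: str = "main"
    per_capita: float = 0.0  # adult per-capita consumption, g/day (0 = no up-shift)
    spillage_fraction: float = cons.DEFAULT_SPILLAGE
    standard_drink_g: float = expo.STANDARD_DRINK_G
    sd_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(cons.DEFAULT_SD_COEFFICIENTS)
    )
    intake_model: str = "gamma"  # "gamma" or "point"
    grid_low: float = 0.1  # g/day, quadrature grid for the average component
    grid_high: float = 250.0
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.intake_model not in ("gamma", "point"):
            raise ValueError("intake_model must be 'gamma' or 'point'")
        if not (0 < self.grid_low < self.grid_high and self.grid_step > 0):
            raise ValueError("invalid integration grid")

    def binge_dose_for(self, summary: ConsumptionSummary) -> float:
        """Grams per binge occasion for one stratum under this scenario."""
        if self.scenario == "SA_III":
            if summary.binge_dose is None:
                raise ValueError(
                    f"scenario SA_III needs a per-group binge_dose; missing for "
                    f"{summary.age_group}/{summary.sex}"
                )
            return summary.binge_dose
        men, women = SCENARIO_BINGE_DRINKS[self.scenario]
        drinks = men if summary.sex == "M" else women
        return drinks * self.standard_drink_g

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return np.linspace(self.grid_low, self.grid_high, n)


@dataclass
class AAFEstimate:
    """Point AAF for one stratum and cause, with optional percentile CI."""

    age_group: str
    sex: str
    cause: str
    injury_class: str
    aaf_binge: float
    aaf_average: float
    aaf_total: float
    deaths: float = 0.0
    attributable_deaths: float = 0.0
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("aaf_binge", "aaf_average", "aaf_total"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.aaf_total <= self.ci_high:
                raise ValueError("CI must bracket the point estimate")


@dataclass
class InputBundle:
    """Everything one scenario run needs.

    ``mortality`` has columns (cause, age_group, sex, deaths); missing
    strata are reported by :func:`run_scenario`, not silently dropped.
    """

    summaries: List[ConsumptionSummary]
    mortality: pd.DataFrame
    curves: Mapping[str, RiskCurve]  # keyed by injury class
    metabolism: MetabolismModel = field(default_factory=MetabolismModel)
    cause_map: CauseMap = field(default_factory=default_cause_map)


def aaf_categorical(prevalences: Sequence[float], rrs: Sequence[float]) -> float:
    """Categorical attributable fraction sum(P_i (RR_i - 1)) / (sum + 1).

    Group 0 is the reference (its RR is conventionally 1).  Prevalences
    must sum to 1; relative risks must be positive.
    """
    p = np.asarray(prevalences, dtype=float)
    r = np.asarray(rrs, dtype=float)
    if p.shape != r.shape:
        raise ValueError("prevalences and rrs must have the same length")
    if np.any(p < 0):
        raise ValueError("prevalences must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"prevalences must sum to 1, got {p.sum()}")
    if np.any(r <= 0):
        raise ValueError("relative risks must be positive")
    excess = float(p @ (r - 1.0))
    return excess / (excess + 1.0)


def rr_binge_adjusted(crude_rr: float, p_day_at_risk: float, p_days_at_risk: float) -> float:
    """Binge RR corrected for time at risk and for occasion frequency.

    ``1 + (RR - 1) * p_day * p_days``: the exposure-weighted mixture of
    at-risk time (relative risk RR) and sober time (relative risk 1).
    """
    _check_adjust_args(crude_rr, p_day_at_risk)
    if not 0.0 <= p_days_at_risk <= 1.0:
        raise ValueError("p_days_at_risk must lie in [0, 1]")
    return 1.0 + (crude_rr - 1.0) * p_day_at_risk * p_days_at_risk


def rr_average_adjusted(crude_rr, p_day_at_risk):
    """Average-volume RR corrected for time at risk only.

    Daily consumption happens every day, so no occasion-frequency factor
    is applied.  Vectorised over both arguments.
    """
    _check_adjust_args(crude_rr, p_day_at_risk)
    return 1.0 + (np.asarray(crude_rr) - 1.0) * np.asarray(p_day_at_risk)


def _check_adjust_args(crude_rr, p_day) -> None:
    if np.any(np.asarray(crude_rr) < 1.0):
        raise ValueError("crude relative risk below 1 is not valid for injury causes")
    p = np.asarray(p_day)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_day_at_risk must lie in [0, 1]")


def aaf_binge(
    summary: ConsumptionSummary,
    curve: RiskCurve,
    model: MetabolismModel,
    scenario: ScenarioConfig,
) -> float:
    """Binge-drinking attributable fraction for one stratum and risk class."""
    dose = scenario.binge_dose_for(summary)
    crude = rr_crude(curve, dose)
    adj = rr_binge_adjusted(
        crude,
        expo.p_day_at_risk(model, dose),
        expo.p_days_at_risk(summary.binge_occasions_per_year),
    )
    prevalences = (
        summary.p_abstainer_former,
        summary.p_current_nonbinge,
        summary.binge_prevalence,
    )
    return aaf_categorical(prevalences, (1.0, 1.0, adj))


def aaf_average(
    summary: ConsumptionSummary,
    dist: IntakeDist,
    curve: RiskCurve,
    model: MetabolismModel,
    grid: Optional[np.ndarray] = None,
) -> float:
    """Average-daily-consumption attributable fraction for one stratum.

    For a gamma intake distribution the excess-risk integral

        A = P_current * Int pdf(x) * (RR_avg(x) - 1) dx

    is evaluated by the trapezoid rule on ``grid`` (default: the
    0.1-250 g/day grid at 0.05 g steps); for a point mass the integral
    collapses to exact arithmetic.  Returns ``A / (A + 1)``.
    """
    if summary.p_current == 0:
        return 0.0
    if isinstance(dist, PointMassConsumption):
        excess = _excess_at(dist.at, curve, model)
        a = summary.p_current * excess
    else:
        x = grid if grid is not None else ScenarioConfig().grid()
        integrand = dist.pdf(x) * _excess_at(x, curve, model)
        if not np.all(np.isfinite(integrand)):
            raise ValueError("non-finite integrand in average-consumption AAF")
        a = summary.p_current * float(np.trapezoid(integrand, x))
    return a / (a + 1.0)


def _excess_at(x, curve: RiskCurve, model: MetabolismModel):
    """Excess adjusted relative risk RR_avg(x) - 1 at daily intake x (vectorised)."""
    return (rr_crude(curve, x) - 1.0) * expo.p_day_at_risk(model, x)


def combine_aaf(
    aaf_binge_val: float,
    aaf_average_val: float,
    deaths: float,
    *,
    age_group: str = "",
    sex: str = "",
    cause: str = "",
    injury_class: str = "",
) -> AAFEstimate:
    """Add the binge and average components (clipped at 1) and convert to deaths."""
    for name, v in (("aaf_binge", aaf_binge_val), ("aaf_average", aaf_average_val)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    total = min(aaf_binge_val + aaf_average_val, 1.0)
    return AAFEstimate(
        age_group=age_group,
        sex=sex,
        cause=cause,
        injury_class=injury_class,
        aaf_binge=aaf_binge_val,
        aaf_average=aaf_average_val,
        aaf_total=total,
        deaths=deaths,
        attributable_deaths=total * deaths,
    )


def wholly_attributable(cause_icd10: str) -> float:
    """AAF = 1 by definition for the alcohol-poisoning codes X45 and X65."""
    code = cause_icd10.strip().upper()
    if code not in ("X45", "X65"):
        raise ValueError(
            f"{cause_icd10!r} is not a wholly alcohol-attributable cause; "
            "use the general binge/average pathway"
        )
    return 1.0


def aggregate_aaf(aafs: Sequence[float], deaths: Sequence[float]) -> float:
    """Death-weighted mean AAF across strata: total attributable / total deaths."""
    a = np.asarray(aafs, dtype=float)
    d = np.asarray(deaths, dtype=float)
    if a.shape != d.shape:
        raise ValueError("aafs and deaths must have the same length")
    if np.any(d < 0):
        raise ValueError("deaths must be non-negative")
    if d.sum() == 0:
        raise ValueError("cannot aggregate: total deaths are zero")
    return float((a * d).sum() / d.sum())


def _class_aafs(
    summary: ConsumptionSummary,
    dist: IntakeDist,
    bundle: InputBundle,
    scenario: ScenarioConfig,
    grid: np.ndarray,
) -> Dict[str, Tuple[float, float]]:
    """(aaf_binge, aaf_average) per risk class for one stratum."""
    out: Dict[str, Tuple[float, float]] = {}
    for cls in (MVA, NON_MVA):
        curve = bundle.curves[cls]
        out[cls] = (
            aaf_binge(summary, curve, bundle.metabolism, scenario),
            aaf_average(summary, dist, curve, bundle.metabolism, grid=grid),
        )
    return out


def _intake_distribution(summary: ConsumptionSummary, scenario: ScenarioConfig) -> IntakeDist:
    mean = summary.mean_for_risk
    if scenario.intake_model == "point" or mean == 0:
        return PointMassConsumption(at=mean)
    if summary.gamma_shape is not None:
        # MC draws perturb the shape; the scale is re-derived from the mean
        return GammaConsumption(shape=summary.gamma_shape, scale=mean / summary.gamma_shape)
    sd = cons.sd_from_mean(mean, scenario.sd_coefficients[summary.sex])
    return cons.fit_gamma(mean, sd)


def run_scenario(bundle: InputBundle, scenario: ScenarioConfig) -> List[AAFEstimate]:
    """Compute the full cause x age x sex AAF grid for one scenario.

    Applies the coverage up-shift (when ``scenario.per_capita`` is set),
    fits each stratum's intake distribution, computes the binge and
    average components per risk class, and assigns them to every cause
    present in the mortality table.  Wholly attributable causes get
    AAF = 1.  Mortality rows whose stratum lacks a consumption summary
    raise an error naming the missing strata.
    """
    summaries = bundle.summaries
    if scenario.per_capita > 0:
        factor, summaries = cons.coverage_upshift(
            summaries, scenario.per_capita, scenario.spillage_fraction
        )
        log.info("coverage up-shift factor %.4f applied to %d strata", factor, len(summaries))
    by_group = {s.group: s for s in summaries}

    mort = bundle.mortality
    missing = sorted(
        {(a, s) for a, s in zip(mort["age_group"], mort["sex"])} - set(by_group)
    )
    if missing:
        raise ValueError(f"mortality table references strata without consumption data: {missing}")

    grid = scenario.grid()
    class_cache: Dict[Tuple[str, str], Dict[str, Tuple[float, float]]] = {}
    estimates: List[AAFEstimate] = []
    for row in mort.itertuples(index=False):
        group = (row.age_group, row.sex)
        summary = by_group[group]
        cause = row.cause
        injury_class = bundle.cause_map.injury_class(cause)
        if injury_class == WHOLLY:
            est = AAFEstimate(
                age_group=row.age_group,
                sex=row.sex,
                cause=cause,
                injury_class=injury_class,
                aaf_binge=0.0,
                aaf_average=1.0,
                aaf_total=1.0,
                deaths=float(row.deaths),
                attributable_deaths=float(row.deaths),
            )
        else:
            if group not in class_cache:
                dist = _intake_distribution(summary, scenario)
                class_cache[group] = _class_aafs(summary, dist, bundle, scenario, grid)
            b, avg = class_cache[group][injury_class]
            est = combine_aaf(
                b,
                avg,
                float(row.deaths),
                age_group=row.age_group,
                sex=row.sex,
                cause=cause,
                injury_class=injury_class,
            )
        estimates.append(est)
    return estimates


def estimates_to_frame(estimates: Iterable[AAFEstimate]) -> pd.DataFrame:
    """Tabulate a list of estimates (one row per stratum x cause)."""
    rows = [
        {
            "age_group": e.age_group,
            "sex": e.sex,
            "cause": e.cause,
            "injury_class": e.injury_class,
            "aaf_binge": e.aaf_binge,
            "aaf_average": e.aaf_average,
            "aaf_total": e.aaf_total,
            "deaths": e.deaths,
            "attributable_deaths": e.attributable_deaths,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def aggregate_by_cause(estimates: Sequence[AAFEstimate]) -> pd.DataFrame:
    """Cause-level death-weighted AAFs (men and women combined)."""
    frame = estimates_to_frame(estimates)
    out = []
    for cause, grp in frame.groupby("cause", sort=False):
        out.append(
            {
                "cause": cause,
                "injury_class": grp["injury_class"].iloc[0],
                "aaf_total": aggregate_aaf(grp["aaf_total"], grp["deaths"]),
                "deaths": grp["deaths"].sum(),
                "attributable_deaths": grp["attributable_deaths"].sum(),
            }
        )
    return pd.DataFrame(out)
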