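"""Monte Carlo uncertainty propagation for attributable fractions.

Confidence intervals are obtained by re-computing every AAF from
randomly regenerated *lowest-level* parameters — the quantities from
which everything else is derived — and taking empirical percentiles of
the resulting distribution (default 2.5th/97.5th of 10,000 draws).

Per draw, one internally consistent input bundle is generated:

* drinker-status prevalences from a Dirichlet over the stratum's
  (abstainer+former, current non-binge, binge) pseudo-counts;
* stratum mean daily intakes from zero-truncated normals on
  (mean, standard error);
* the coverage factor re-derived from the drawn population mean against
  90% of per-capita consumption, so the up-shift co-varies with the
  drawn survey means;
* the gamma shape from a mean-preserving lognormal around its point
  value, with the scale re-derived from the drawn up-shifted mean;
* risk-curve log-coefficients from normals on (beta, se_beta);
* binge occasions per year, optionally negative-binomial or lognormal.

Draws that land outside the parameter space (non-positive coefficient,
occasions above 365) are resampled rather than clipped, preserving the
declared marginals; their count is logged and a warning raised if they
exceed 1% of draws.  Percentile rather than normal-approximation
intervals are used because AAF distributions are skewed near 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import consumption as cons
from . import exposure_time as expo
from .aaf_engine import (
    AAFEstimate,
    InputBundle,
    ScenarioConfig,
    estimates_to_frame,
    run_scenario,
)
from .causes import WHOLLY
from .consumption import ConsumptionSummary
from .exposure_time import DAYS_PER_YEAR

__all__ = ["MCSettings", "draw_parameters", "mc_confidence_interval", "percentile_interval"]

log = logging.getLogger("injury_aaf")


@dataclass(frozen=True)
class MCSettings:
    """Variance specification and controls for the Monte Carlo propagation.

    Every stochastic input has a declared family and dispersion; a zero
    or absent dispersion fixes that input at its point value, so an
    all-zero specification collapses the interval onto the point
    estimate.

    Parameters
    ----------
    seed
        Seed of the random generator; identical seeds give identical
        intervals.
    n_draws
        Number of regenerated AAF sets (default 10,000).
    ci_level
        Central coverage of the percentile interval (default 0.95).
    prevalence_ess
        Effective sample size per stratum: the Dirichlet pseudo-count
        total over the three drinker-status groups.  ``None`` fixes the
        prevalences.
    vary_means
        Draw stratum means from zero-truncated normals using each
        summary's ``raw_mean_se``; a missing (NaN) standard error is
        rejected.
    beta_se
        Standard error of the risk-curve coefficient per injury class
        (from the meta-regression); classes not listed are fixed.
    shape_cv
        Coefficient of variation of the lognormal draw of the gamma
        shape parameter (0 = fixed).
    occasions_family
        ``"fixed"``, ``"negbin"`` (dispersion = size parameter) or
        ``"lognormal"`` (dispersion = CV) for binge occasions per year.
    """

    seed: int
    n_draws: int = 10000
    ci_level: float = 0.95
    prevalence_ess: Optional[float] = None
    vary_means: bool = True
    beta_se: Mapping[str, float] = field(default_factory=dict)
    shape_cv: float = 0.0
    occasions_family: str = "fixed"
    occasions_dispersion: float = 0.0
    max_degenerate_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.occasions_family not in ("fixed", "negbin", "lognormal"):
            raise ValueError(f"unknown occasions family {self.occasions_family!r}")
        if self.occasions_family != "fixed" and self.occasions_dispersion <= 0:
            raise ValueError(
                f"occasions family {self.occasions_family!r} needs a positive dispersion"
            )


def percentile_interval(samples: np.ndarray, ci_level: float) -> Tuple[float, float]:
    """Empirical central interval: linear-interpolated order statistics."""
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(np.asarray(samples, dtype=float), [alpha, 1.0 - alpha], axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# Vectorised parameter draws (one array per parameter, n_draws long)


def _truncnorm_draws(rng: np.random.Generator, mean: float, se: float, n: int) -> np.ndarray:
    """Zero-truncated normal via inverse-CDF (exact, no rejection)."""
    if se == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / se
    return stats.truncnorm.ppf(rng.random(n), a=a, b=np.inf, loc=mean, scale=se)


def _dirichlet_draws(
    rng: np.random.Generator, probs: Sequence[float], ess: float, n: int
) -> np.ndarray:
    """Dirichlet draws on the (abst+former, non-binge, binge) simplex.

    Components with zero point prevalence stay exactly zero (a Dirichlet
    cannot place mass on a zero pseudo-count).
    """
    probs_arr = np.asarray(probs, dtype=float)
    out = np.zeros((n, probs_arr.size))
    pos = probs_arr > 0
    if pos.sum() == 1:
        out[:, pos] = 1.0
        return out
    out[:, pos] = rng.dirichlet(ess * probs_arr[pos], size=n)
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _resample(
    rng: np.random.Generator, draw_fn, valid_fn, n: int, what: str, max_iter: int = 100
) -> Tuple[np.ndarray, int]:
    """Draw n values, resampling invalid entries; returns (values, n_resampled)."""
    values = draw_fn(n)
    bad = ~valid_fn(values)
    total_bad = int(bad.sum())
    it = 0
    while bad.any():
        it += 1
        if it > max_iter:
            raise RuntimeError(f"could not draw valid values for {what}")
        redraw = draw_fn(int(bad.sum()))
        values = np.array(values)
        values[bad] = redraw
        bad = ~valid_fn(values)
        total_bad += int(bad.sum())
    return values, total_bad


@dataclass
class _GroupDraws:
    """All drawn lowest-level parameters for one stratum."""

    prevalences: np.ndarray  # (n, 3): abst+former, non-binge, binge
    raw_mean: np.ndarray  # (n,)
    occasions: np.ndarray  # (n,)
    shape_factor: np.ndarray  # (n,) multiplier on the point gamma shape


def _draw_group(
    rng: np.random.Generator,
    summary: ConsumptionSummary,
    settings: MCSettings,
    n: int,
) -> Tuple[_GroupDraws, int]:
    degenerate = 0
    point_prev = (
        summary.p_abstainer_former,
        summary.p_current_nonbinge,
        summary.binge_prevalence,
    )
    if settings.prevalence_ess is not None:
        prev = _dirichlet_draws(rng, point_prev, settings.prevalence_ess, n)
    else:
        prev = np.tile(point_prev, (n, 1))

    if settings.vary_means:
        se = summary.raw_mean_se
        if not np.isfinite(se):
            raise ValueError(
                f"summary {summary.age_group}/{summary.sex} lacks a standard error "
                "for its mean; declare raw_mean_se or set vary_means=False"
            )
        raw_mean = _truncnorm_draws(rng, summary.raw_mean, se, n)
    else:
        raw_mean = np.full(n, summary.raw_mean)

    occ = np.full(n, summary.binge_occasions_per_year)
    if settings.occasions_family != "fixed" and summary.binge_occasions_per_year > 0:
        m = summary.binge_occasions_per_year
        if settings.occasions_family == "negbin":
            k = settings.occasions_dispersion
            draw = lambda nn: rng.negative_binomial(k, k / (k + m), size=nn).astype(float)
        else:
            draw = lambda nn: m * _lognormal_factor(rng, settings.occasions_dispersion, nn)
        occ, bad = _resample(rng, draw, lambda v: v <= DAYS_PER_YEAR, n, "binge occasions")
        degenerate += bad

    shape_factor = _lognormal_factor(rng, settings.shape_cv, n)
    return _GroupDraws(prev, raw_mean, occ, shape_factor), degenerate


def _draw_betas(
    rng: np.random.Generator,
    bundle: InputBundle,
    settings: MCSettings,
    n: int,
) -> Tuple[Dict[str, np.ndarray], int]:
    betas: Dict[str, np.ndarray] = {}
    degenerate = 0
    for cls, curve in bundle.curves.items():
        se = settings.beta_se.get(cls, 0.0)
        if se > 0:
            draw = lambda nn: rng.normal(curve.coefficient, se, size=nn)
            betas[cls], bad = _resample(rng, draw, lambda v: v > 0, n, f"beta[{cls}]")
            degenerate += bad
        else:
            betas[cls] = np.full(n, curve.coefficient)
    return betas, degenerate


def draw_parameters(
    bundle: InputBundle,
    settings: MCSettings,
    index: int = 0,
    rng: Optional[np.random.Generator] = None,
    scenario: Optional[ScenarioConfig] = None,
) -> InputBundle:
    """One internally consistent perturbed input bundle.

    Deterministic in ``(settings.seed, index)``.  With all dispersions
    zero the returned bundle equals the point inputs.  The drawn gamma
    shape is carried on each summary's ``gamma_shape`` field so the
    scale is re-derived downstream from the drawn up-shifted mean.
    """
    if rng is None:
        rng = np.random.default_rng([settings.seed, index])
    betas, _ = _draw_betas(rng, bundle, settings, 1)
    point_shapes = _point_shapes((scenario or ScenarioConfig()).sd_coefficients)
    new_summaries = []
    for s in bundle.summaries:
        g, _ = _draw_group(rng, s, settings, 1)
        p_abst, p_nonbinge, p_binge = g.prevalences[0]
        new_summaries.append(
            replace(
                s,
                p_abstainer_former=p_abst,
                p_current=p_nonbinge + p_binge,
                binge_prevalence=p_binge,
                raw_mean=float(g.raw_mean[0]),
                binge_occasions_per_year=float(g.occasions[0]),
                corrected_mean=None,
                gamma_shape=point_shapes[s.sex] * float(g.shape_factor[0]),
            )
        )
    new_curves = {
        cls: curve.with_coefficient(float(betas[cls][0]))
        for cls, curve in bundle.curves.items()
    }
    return replace(bundle, summaries=new_summaries, curves=new_curves)


def _point_shapes(sd_coefficients: Mapping[str, float]) -> Dict[str, float]:
    """Point gamma shape per sex implied by the sd(mean) regression: 1/c^2."""
    # sd = c * mean  =>  shape = (mean/sd)^2 = c^-2, independent of the mean
    return {sex: 1.0 / c**2 for sex, c in sd_coefficients.items()}


# ---------------------------------------------------------------------------
# Vectorised AAF recomputation


def _capped_transform(x, curve):
    return np.minimum(x, curve.dose_cap) ** curve.dose_power


def mc_confidence_interval(
    bundle: InputBundle,
    scenario: ScenarioConfig,
    settings: MCSettings,
    return_draws: bool = False,
):
    """Point AAFs from the unperturbed inputs plus percentile CIs per cell.

    The per-draw recomputation is vectorised across draws: for every
    stratum the drawn prevalences, means, occasions, shapes and
    coefficients are generated as arrays, the coverage factor is
    re-derived per draw from the drawn population mean, and the binge
    and average components are evaluated for each draw with exactly the
    engine's formulas (trapezoid quadrature on the scenario grid for the
    gamma intake model, closed form for the point-mass model).

    Returns the list of :class:`AAFEstimate` with ``ci_low``/``ci_high``
    filled; with ``return_draws=True`` also the (n_draws, n_cells) array
    of recomputed total AAFs.
    """
    point = run_scenario(bundle, scenario)
    n = settings.n_draws
    rng = np.random.default_rng(settings.seed)

    betas, degenerate = _draw_betas(rng, bundle, settings, n)
    group_draws: Dict[Tuple[str, str], _GroupDraws] = {}
    sd_coeffs = scenario.sd_coefficients
    for s in bundle.summaries:
        group_draws[s.group], bad = _draw_group(rng, s, settings, n)
        degenerate += bad

    frac_bad = degenerate / max(n, 1)
    if frac_bad > settings.max_degenerate_frac:
        log.warning(
            "%.2f%% of Monte Carlo draws were degenerate and resampled", 100 * frac_bad
        )

    # Coverage factor per draw from the drawn population mean
    if scenario.per_capita > 0:
        weights = np.array([s.population for s in bundle.summaries])
        drinker_means = np.stack(
            [
                group_draws[s.group].prevalences[:, 1:].sum(axis=1)
                * group_draws[s.group].raw_mean
                for s in bundle.summaries
            ]
        )  # (n_groups, n)
        pop_mean = weights @ drinker_means / weights.sum()
        factor = (1.0 - scenario.spillage_fraction) * scenario.per_capita / pop_mean
    else:
        factor = np.ones(n)

    grid = scenario.grid()
    metab = bundle.metabolism
    p_day_grid = expo.p_day_at_risk(metab, grid)

    # Per stratum and injury class, (n,) arrays of total AAF draws
    class_draws: Dict[Tuple[Tuple[str, str], str], np.ndarray] = {}
    classes = list(bundle.curves)
    for s in bundle.summaries:
        g = group_draws[s.group]
        corrected = g.raw_mean * factor
        p_binge = g.prevalences[:, 2]
        p_current = g.prevalences[:, 1:].sum(axis=1)
        p_days = g.occasions / DAYS_PER_YEAR
        dose = scenario.binge_dose_for(s)
        p_day_binge = expo.p_day_at_risk(metab, dose)

        avg_a = {cls: np.empty(n) for cls in classes}
        if scenario.intake_model == "point":
            p_day_mean = expo.p_day_at_risk(metab, corrected)
            for cls, curve in bundle.curves.items():
                t0 = _capped_transform(corrected, curve)
                avg_a[cls] = p_current * (np.exp(betas[cls] * t0) - 1.0) * p_day_mean
        else:
            shape0 = 1.0 / sd_coeffs[s.sex] ** 2
            shapes = shape0 * g.shape_factor
            scales = corrected / shapes
            t_grids = {cls: _capped_transform(grid, c) for cls, c in bundle.curves.items()}
            chunk = 512
            for lo in range(0, n, chunk):
                hi = min(lo + chunk, n)
                pdf = stats.gamma.pdf(
                    grid[None, :], a=shapes[lo:hi, None], scale=scales[lo:hi, None]
                )
                for cls in classes:
                    excess = (
                        np.exp(betas[cls][lo:hi, None] * t_grids[cls][None, :]) - 1.0
                    ) * p_day_grid
                    avg_a[cls][lo:hi] = p_current[lo:hi] * np.trapezoid(
                        pdf * excess, grid, axis=1
                    )

        for cls, curve in bundle.curves.items():
            crude_binge = np.exp(betas[cls] * _capped_transform(dose, curve))
            rr_b = 1.0 + (crude_binge - 1.0) * p_day_binge * p_days
            excess_b = p_binge * (rr_b - 1.0)
            aaf_b = excess_b / (excess_b + 1.0)
            a = avg_a[cls]
            aaf_avg = a / (a + 1.0)
            class_draws[(s.group, cls)] = np.minimum(aaf_b + aaf_avg, 1.0)

    # Assemble per-cell draw matrix in the order of the point estimates
    draws = np.empty((n, len(point)))
    for j, est in enumerate(point):
        if est.injury_class == WHOLLY:
            draws[:, j] = 1.0
        else:
            draws[:, j] = class_draws[((est.age_group, est.sex), est.injury_class)]

    lo, hi = percentile_interval(draws, settings.ci_level)
    out = []
    for j, est in enumerate(point):
        out.append(
            replace(
                est,
                ci_low=float(min(lo[j], est.aaf_total)),
                ci_high=float(max(hi[j], est.aaf_total)),
            )
        )
    if return_draws:
        return out, draws
    return out
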