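"""Dose-response relative-risk curves for acute injury mortality.

The crude relative risk of dying from an injury while alcohol is
pharmacologically active is modelled as a one-parameter log-linear
function of the dose consumed in a single occasion,

    ln RR(x) = beta * x**p,    x in grams of pure ethanol per occasion,

with ``p = 2`` for motor-vehicle (MVA) injury and ``p = 0.5`` for all
non-motor-vehicle (non-MVA) injury combined.  These forms arise from
fractional-polynomial meta-regression of case-control and case-crossover
studies; because risk data are scarce above roughly 100 g per occasion,
the curve is evaluated at a capped dose (default 108 g) for any larger
intake.

Curves are calibrated from published (dose, RR) anchor pairs by least
squares through the origin on the log scale, which enforces RR(0) = 1
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["RiskCurve", "rr_crude", "calibrate_curve", "MVA", "NON_MVA"]

MVA = "MVA"
NON_MVA = "nonMVA"

#: Canonical exponents of the two published curve families.
DEFAULT_DOSE_POWER = {MVA: 2.0, NON_MVA: 0.5}

#: Dose (g/occasion) above which the curve is evaluated at the cap.
DEFAULT_DOSE_CAP = 108.0


@dataclass(frozen=True)
class RiskCurve:
    """One-parameter log-linear dose-response curve ``ln RR = beta * x**p``.

    Parameters
    ----------
    injury_class
        ``"MVA"`` or ``"nonMVA"``.
    dose_power
        Exponent ``p`` applied to the per-occasion dose (dimensionless).
    coefficient
        ``beta`` in ``ln RR = beta * x**p``; units ``(g/occasion)**-p``.
        Must be positive so that RR is non-decreasing and RR >= 1.
    dose_cap
        Grams per occasion beyond which the curve is evaluated at the cap.
    max_residual
        Largest absolute log-scale residual observed at calibration
        (0 for a curve specified directly).
    """

    injury_class: str
    dose_power: float
    coefficient: float
    dose_cap: float = DEFAULT_DOSE_CAP
    max_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError(f"coefficient must be > 0, got {self.coefficient}")
        if self.dose_cap <= 0:
            raise ValueError(f"dose_cap must be > 0, got {self.dose_cap}")

    def __call__(self, dose):
        return rr_crude(self, dose)

    def with_coefficient(self, coefficient: float) -> "RiskCurve":
        """Same curve with a substituted coefficient (used by MC draws)."""
        return replace(self, coefficient=coefficient, max_residual=0.0)


def rr_crude(curve: RiskCurve, dose):
    """Crude relative risk at ``dose`` grams of ethanol per occasion.

    The crude RR compares time during which alcohol is active against
    sober time; it is *not* yet adjusted for the fraction of time
    actually spent at risk (see :mod:`injury_aaf.aaf_engine`).  Doses
    above ``curve.dose_cap`` are evaluated at the cap.

    Accepts scalars or arrays; negative doses are rejected.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative (grams per occasion)")
    capped = np.minimum(dose_arr, curve.dose_cap)
    rr = np.exp(curve.coefficient * capped**curve.dose_power)
    if np.ndim(dose) == 0:
        return float(rr)
    return rr


def calibrate_curve(
    anchors: Iterable[Sequence[float]],
    dose_power: float,
    injury_class: str = NON_MVA,
    dose_cap: float = DEFAULT_DOSE_CAP,
) -> RiskCurve:
    """Fit ``ln RR = beta * x**p`` through the origin to (dose, RR) anchors.

    beta is the closed-form least-squares solution

        beta = sum(x**p * ln RR) / sum(x**(2p))

    which is exact for a single anchor and enforces RR(0) = 1.  The
    fitted curve's ``max_residual`` records the largest absolute
    log-scale misfit over the anchors, so a caller can verify that the
    one-parameter family actually describes its data.

    Raises
    ------
    ValueError
        If no anchors are given, or any anchor has dose <= 0 or RR <= 1.
    """
    pairs = [(float(d), float(r)) for d, r in anchors]
    if not pairs:
        raise ValueError("at least one (dose, rr) anchor is required")
    doses = np.array([d for d, _ in pairs])
    rrs = np.array([r for _, r in pairs])
    if np.any(doses <= 0):
        raise ValueError("anchor doses must be positive")
    if np.any(rrs <= 1):
        raise ValueError("anchor relative risks must exceed 1")
    t = doses**dose_power
    log_rr = np.log(rrs)
    beta = float(t @ log_rr) / float(t @ t)
    residuals = log_rr - beta * t
    return RiskCurve(
        injury_class=injury_class,
        dose_power=dose_power,
        coefficient=beta,
        dose_cap=dose_cap,
        max_residual=float(np.max(np.abs(residuals))),
    )
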