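"""Time-at-risk from hepatic alcohol clearance.

Injury risk is elevated only while alcohol is pharmacologically active,
so the crude relative risk must be down-weighted by the fraction of time
a drinker actually spends at risk.  The liver clears alcohol at a
roughly constant rate, so the duration of the risk period grows with the
number of drinks consumed in one occasion: one Canadian standard drink
(13.6 g ethanol) carries a risk period of about 30 minutes, three drinks
about 3 hours.  A day therefore contains ``floor(24 / duration)``
possible risk periods — 48 for one drink, 8 for three.

The duration model is a piecewise-linear interpolation through an anchor
table ``(drinks, hours)``, anchored at (0, 0), linearly extrapolated
beyond the last anchor and clamped to [0, 24].  The anchors are
configurable so a blood-alcohol-threshold clearance model can be swapped
in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "MetabolismModel",
    "risk_duration",
    "risk_periods_per_day",
    "p_day_at_risk",
    "p_days_at_risk",
]

#: Canadian standard drink, grams of pure ethanol.
STANDARD_DRINK_G = 13.6

DEFAULT_ANCHORS: Tuple[Tuple[float, float], ...] = ((1.0, 0.5), (3.0, 3.0))

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class MetabolismModel:
    """Risk-period duration as a function of drinks per occasion.

    ``anchor_points`` are (drinks, hours) pairs, strictly increasing in
    both coordinates; (0, 0) is implicit.  Defaults are the two
    experimentally grounded anchors (1 drink, 0.5 h) and (3 drinks, 3 h).
    """

    anchor_points: Tuple[Tuple[float, float], ...] = DEFAULT_ANCHORS
    standard_drink_g: float = STANDARD_DRINK_G
    day_hours: float = 24.0
    _xp: np.ndarray = field(init=False, repr=False, compare=False)
    _yp: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = [(float(d), float(h)) for d, h in self.anchor_points]
        if not pts:
            raise ValueError("at least one anchor point is required")
        drinks = np.array([d for d, _ in pts])
        hours = np.array([h for _, h in pts])
        if np.any(drinks <= 0) or np.any(hours <= 0):
            raise ValueError("anchor drinks and hours must be positive")
        if np.any(np.diff(drinks) <= 0) or np.any(np.diff(hours) <= 0):
            raise ValueError("anchors must be strictly increasing in both coordinates")
        if np.any(hours > self.day_hours):
            raise ValueError(f"anchor durations must not exceed {self.day_hours} h")
        object.__setattr__(self, "_xp", np.concatenate([[0.0], drinks]))
        object.__setattr__(self, "_yp", np.concatenate([[0.0], hours]))


def risk_duration(model: MetabolismModel, drinks):
    """Hours of elevated risk after ``drinks`` standard drinks in one occasion.

    Piecewise-linear through the anchor table (with duration(0) = 0),
    linear extrapolation beyond the last anchor using the final segment
    slope, clamped to [0, 24].  Fractional drink counts are allowed.
    """
    d = np.asarray(drinks, dtype=float)
    if np.any(d < 0):
        raise ValueError("drinks must be non-negative")
    xp, yp = model._xp, model._yp
    dur = np.interp(d, xp, yp)
    if len(xp) >= 2:
        slope = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        beyond = d > xp[-1]
        dur = np.where(beyond, yp[-1] + slope * (d - xp[-1]), dur)
    dur = np.clip(dur, 0.0, model.day_hours)
    return float(dur) if np.ndim(drinks) == 0 else dur


def risk_periods_per_day(model: MetabolismModel, drinks) -> int:
    """Number of possible individual risk periods in a 24-hour day.

    ``floor(24 / duration)``: a count, so 3 drinks (3 h) -> 8 periods,
    1 drink (0.5 h) -> 48.  Undefined (rejected) at zero duration.
    """
    dur = risk_duration(model, drinks)
    d = np.asarray(dur, dtype=float)
    if np.any(d <= 0):
        raise ValueError("risk duration is zero; periods per day undefined")
    periods = np.floor(model.day_hours / d).astype(int)
    return int(periods) if np.ndim(drinks) == 0 else periods


def p_day_at_risk(model: MetabolismModel, dose):
    """Proportion of a day at risk after consuming ``dose`` grams in one occasion.

    ``risk_duration(dose / standard_drink_g) / 24``, in [0, 1]; reaches 1
    when the duration saturates at 24 h.
    """
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative")
    return risk_duration(model, dose_arr / model.standard_drink_g) / model.day_hours


def p_days_at_risk(occasions_per_year) -> float:
    """Proportion of days on which drinking occurs: occasions / 365.

    Daily average consumption uses 365 occasions (= every day), giving 1.
    """
    occ = np.asarray(occasions_per_year, dtype=float)
    if np.any(occ < 0) or np.any(occ > DAYS_PER_YEAR):
        raise ValueError("occasions_per_year must lie in [0, 365]")
    out = occ / DAYS_PER_YEAR
    return float(out) if np.ndim(occasions_per_year) == 0 else out
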