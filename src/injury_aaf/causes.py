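"""ICD-10 injury cause grouping.

Maps ICD-10 codes to the injury categories used in the attributable-
fraction calculation, and to the risk class each category draws its
dose-response curve from: ``MVA`` (motor-vehicle), ``nonMVA`` (all other
injury), or ``wholly`` (alcohol-poisoning codes X45/X65 that are
alcohol-attributable by definition, AAF = 1).

Specific codes take precedence over ranges, so X45 maps to alcohol
poisoning even though it lies inside the X40-X49 poisoning range.

The motor-vehicle code set is not standardised across sources; the
default here is the conventional road-traffic subset of the V series,
with the remaining V codes falling to "Other unintentional injuries".
Both it and the "Other intentional injuries" set are overridable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = ["CauseMap", "CauseCategory", "map_cause", "default_cause_map", "WHOLLY"]

WHOLLY = "wholly"

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\d))?$")


def _code_key(code: str) -> Tuple[str, int, Optional[int]]:
    m = _CODE_RE.match(code.strip().upper().replace(" ", ""))
    if not m:
        raise ValueError(f"not a valid ICD-10 code: {code!r}")
    letter, num, sub = m.group(1), int(m.group(2)), m.group(3)
    return letter, num, (int(sub) if sub is not None else None)


def _in_range(code: Tuple[str, int, Optional[int]], lo: str, hi: str) -> bool:
    """True if code lies in the inclusive ICD range [lo, hi] (3-character granularity)."""
    letter, num, sub = code
    lo_l, lo_n, lo_s = _code_key(lo)
    hi_l, hi_n, hi_s = _code_key(hi)
    pos = (letter, num)
    if not ((lo_l, lo_n) <= pos <= (hi_l, hi_n)):
        return False
    # sub-code granularity only matters at the range ends
    if pos == (lo_l, lo_n) and lo_s is not None and (sub is None or sub < lo_s):
        return False
    if pos == (hi_l, hi_n) and hi_s is not None and sub is not None and sub > hi_s:
        return False
    return True


# Default road-traffic subset of the V series (pedestrian/cyclist/occupant
# injured in a traffic accident).  Not printed in the source tables;
# overridable via CauseMap.
ROAD_TRAFFIC_V_CODES: Tuple[Tuple[str, str], ...] = (
    ("V02", "V04"),
    ("V09.0", "V09.2"),
    ("V12", "V14"),
    ("V19.0", "V19.2"),
    ("V19.4", "V19.6"),
    ("V20", "V79"),
    ("V80.3", "V80.5"),
    ("V81.0", "V81.1"),
    ("V82.0", "V82.1"),
    ("V83", "V86"),
    ("V87.0", "V87.8"),
    ("V89.0", "V89.0"),
    ("V89.2", "V89.2"),
)


@dataclass(frozen=True)
class CauseCategory:
    """One injury category: a name, an injury class, and its ICD-10 ranges."""

    name: str
    injury_class: str  # "MVA", "nonMVA" or "wholly"
    ranges: Tuple[Tuple[str, str], ...]  # inclusive (lo, hi) pairs
    priority: int = 0  # higher wins on overlap (specific codes over ranges)

    def contains(self, code: Tuple[str, int, Optional[int]]) -> bool:
        return any(_in_range(code, lo, hi) for lo, hi in self.ranges)


@dataclass(frozen=True)
class CauseMap:
    """Ordered collection of injury categories with precedence on overlap."""

    categories: Tuple[CauseCategory, ...]

    def map_cause(self, icd10: str) -> CauseCategory:
        """Resolve an ICD-10 code to its injury category.

        Raises ``KeyError`` echoing the code when no category matches.
        """
        key = _code_key(icd10)
        hits = [c for c in self.categories if c.contains(key)]
        if not hits:
            raise KeyError(f"ICD-10 code {icd10!r} is not mapped to any injury category")
        return max(hits, key=lambda c: c.priority)

    def injury_class(self, cause_name: str) -> str:
        for c in self.categories:
            if c.name == cause_name:
                return c.injury_class
        raise KeyError(f"unknown cause category {cause_name!r}")

    @property
    def names(self) -> List[str]:
        return [c.name for c in self.categories]


def default_cause_map(
    mva_ranges: Sequence[Tuple[str, str]] = ROAD_TRAFFIC_V_CODES,
    other_intentional_ranges: Sequence[Tuple[str, str]] = (("Y35", "Y36"),),
) -> CauseMap:
    """The standard injury category table.

    X45 and X65 are flagged wholly attributable and take precedence over
    the poisoning and self-harm ranges that contain them.
    """
    cats = [
        CauseCategory("Motor vehicle collision", "MVA", tuple(mva_ranges), priority=1),
        CauseCategory("Poisonings", "nonMVA", (("X40", "X49"),)),
        CauseCategory("Falls", "nonMVA", (("W00", "W19"),)),
        CauseCategory("Fires", "nonMVA", (("X00", "X09"),)),
        CauseCategory(
            "Poisonings and exposure to alcohol", WHOLLY, (("X45", "X45"),), priority=2
        ),
        CauseCategory("Drowning", "nonMVA", (("W65", "W74"),)),
        CauseCategory(
            "Other unintentional injuries",
            "nonMVA",
            (
                ("V01", "V99"),  # non-traffic remainder (traffic subset wins on priority)
                ("W20", "W64"),
                ("W75", "W99"),
                ("X10", "X39"),
                ("X50", "X59"),
                ("Y40", "Y86"),
                ("Y88", "Y89"),
            ),
        ),
        CauseCategory(
            "Self-inflicted injuries", "nonMVA", (("X60", "X84"), ("Y87.0", "Y87.0")), priority=1
        ),
        CauseCategory(
            "Intentional self-poisoning by and exposure to alcohol",
            WHOLLY,
            (("X65", "X65"),),
            priority=2,
        ),
        CauseCategory(
            "Homicide", "nonMVA", (("X85", "Y09"), ("Y87.1", "Y87.1")), priority=1
        ),
        CauseCategory(
            "Other intentional injuries", "nonMVA", tuple(other_intentional_ranges), priority=1
        ),
    ]
    return CauseMap(categories=tuple(cats))


def map_cause(icd10: str, cause_map: Optional[CauseMap] = None) -> CauseCategory:
    """Module-level convenience: resolve a code against the default map."""
    return (cause_map or default_cause_map()).map_cause(icd10)
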