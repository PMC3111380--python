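"""Readers, writers and scenario configuration.

CSV dialects
------------
Consumption table (one row per age x sex stratum)::

    age_group,sex,p_abst_former,p_current,raw_mean_gday,raw_mean_se,
    binge_prev,binge_occasions_yr[,binge_dose_g][,population]

Mortality table (one row per cause x stratum)::

    cause_id,icd10_range,age_group,sex,deaths

``icd10_range`` is resolved against the cause map by its first code, so
a row may carry either a single code ("X45") or a range ("W00-W19").

Schema violations are collected and reported together, each with its
row number.  Result CSVs are stamped with scenario id, seed and package
version as ``#`` comment lines so reruns are traceable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .aaf_engine import InputBundle, ScenarioConfig
from .causes import CauseMap, default_cause_map
from .consumption import ConsumptionSummary
from .exposure_time import MetabolismModel
from .risk_model import RiskCurve
from .synthetic_data import published_anchor_curves
from .uncertainty import MCSettings

__all__ = [
    "read_consumption",
    "read_mortality",
    "read_inputs",
    "write_results",
    "read_results",
    "load_config",
    "write_config",
]

log = logging.getLogger("injury_aaf")

_CONSUMPTION_COLUMNS = (
    "age_group",
    "sex",
    "p_abst_former",
    "p_current",
    "raw_mean_gday",
    "raw_mean_se",
    "binge_prev",
    "binge_occasions_yr",
)


def read_consumption(path: Union[str, Path]) -> List[ConsumptionSummary]:
    """Read and validate a stratum-level consumption CSV."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _CONSUMPTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing consumption columns {missing}")
    summaries, errors = [], []
    for i, row in frame.iterrows():
        try:
            summaries.append(
                ConsumptionSummary(
                    age_group=str(row["age_group"]),
                    sex=str(row["sex"]),
                    p_abstainer_former=float(row["p_abst_former"]),
                    p_current=float(row["p_current"]),
                    raw_mean=float(row["raw_mean_gday"]),
                    raw_mean_se=float(row["raw_mean_se"]),
                    binge_prevalence=float(row["binge_prev"]),
                    binge_occasions_per_year=float(row["binge_occasions_yr"]),
                    binge_dose=(
                        float(row["binge_dose_g"])
                        if "binge_dose_g" in frame.columns and pd.notna(row["binge_dose_g"])
                        else None
                    ),
                    population=(
                        float(row["population"])
                        if "population" in frame.columns and pd.notna(row["population"])
                        else 1.0
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header line and 1-based numbering
    if errors:
        raise ValueError(f"{path}: invalid consumption rows:\n  " + "\n  ".join(errors))
    return summaries


def read_mortality(
    path: Union[str, Path], cause_map: Optional[CauseMap] = None
) -> pd.DataFrame:
    """Read a mortality CSV and resolve each row's ICD-10 range to a cause.

    Returns columns (cause, age_group, sex, deaths) ready for the engine.
    """
    cmap = cause_map or default_cause_map()
    frame = pd.read_csv(path, comment="#")
    required = ("cause_id", "icd10_range", "age_group", "sex", "deaths")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mortality columns {missing}")
    rows, errors = [], []
    for i, row in frame.iterrows():
        try:
            deaths = float(row["deaths"])
            if deaths < 0:
                raise ValueError(f"negative death count {deaths}")
            first_code = str(row["icd10_range"]).split("-")[0].strip()
            category = cmap.map_cause(first_code)
            rows.append(
                {
                    "cause": category.name,
                    "age_group": str(row["age_group"]),
                    "sex": str(row["sex"]),
                    "deaths": deaths,
                }
            )
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid mortality rows:\n  " + "\n  ".join(errors))
    return pd.DataFrame(rows)


def read_inputs(
    consumption_path: Union[str, Path],
    mortality_path: Union[str, Path],
    cause_map: Optional[CauseMap] = None,
    curves: Optional[Dict[str, RiskCurve]] = None,
    metabolism: Optional[MetabolismModel] = None,
) -> InputBundle:
    """Assemble a validated input bundle from the two CSV inputs.

    Mortality strata must all be present in the consumption table; the
    missing ones are enumerated in the error message.
    """
    cmap = cause_map or default_cause_map()
    summaries = read_consumption(consumption_path)
    mortality = read_mortality(mortality_path, cmap)
    have = {(s.age_group, s.sex) for s in summaries}
    referenced = {(a, s) for a, s in zip(mortality["age_group"], mortality["sex"])}
    missing = sorted(referenced - have)
    if missing:
        raise ValueError(
            f"mortality strata missing from the consumption table: {missing}; "
            f"expected strata {sorted(have)}"
        )
    return InputBundle(
        summaries=summaries,
        mortality=mortality,
        curves=curves or published_anchor_curves(),
        metabolism=metabolism or MetabolismModel(),
        cause_map=cmap,
    )


def write_results(
    frame: pd.DataFrame,
    path: Union[str, Path],
    scenario: str,
    seed: Optional[int] = None,
) -> None:
    """Write a results CSV stamped with scenario id, seed and version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# injury-aaf v{__version__}\n")
        fh.write(f"# scenario={scenario} seed={seed}\n")
        frame.to_csv(fh, index=False)
    log.info("wrote %d result rows to %s", len(frame), path)


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)


def _scenario_to_dict(config: ScenarioConfig) -> dict:
    return {
        "scenario": config.scenario,
        "per_capita": config.per_capita,
        "spillage_fraction": config.spillage_fraction,
        "standard_drink_g": config.standard_drink_g,
        "sd_coefficients": dict(config.sd_coefficients),
        "intake_model": config.intake_model,
        "grid": {"low": config.grid_low, "high": config.grid_high, "step": config.grid_step},
    }


def write_config(
    path: Union[str, Path],
    config: ScenarioConfig,
    curves: Optional[Dict[str, RiskCurve]] = None,
    metabolism: Optional[MetabolismModel] = None,
) -> None:
    doc = {"scenario_config": _scenario_to_dict(config)}
    if curves:
        doc["curves"] = {
            cls: {
                "dose_power": c.dose_power,
                "coefficient": c.coefficient,
                "dose_cap": c.dose_cap,
            }
            for cls, c in curves.items()
        }
    if metabolism:
        doc["metabolism"] = {"anchors": [list(a) for a in metabolism.anchor_points]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(
    path: Union[str, Path],
) -> Tuple[ScenarioConfig, Dict[str, RiskCurve], MetabolismModel, Optional[MCSettings]]:
    """Load a scenario YAML: scenario constants, curves, metabolism, MC spec.

    Any omitted block falls back to the package defaults (published
    anchor-calibrated curves, the two-point metabolism anchor table).
    The MC block, if present, must be completed with a seed by the
    caller (``replace(settings, seed=...)``).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sc = doc.get("scenario_config", {})
    grid = sc.pop("grid", {})
    config = ScenarioConfig(
        **sc,
        grid_low=grid.get("low", 0.1),
        grid_high=grid.get("high", 250.0),
        grid_step=grid.get("step", 0.05),
    )
    curves = published_anchor_curves()
    for cls, spec in (doc.get("curves") or {}).items():
        curves[cls] = RiskCurve(injury_class=cls, **spec)
    metab = doc.get("metabolism")
    metabolism = (
        MetabolismModel(anchor_points=tuple(tuple(a) for a in metab["anchors"]))
        if metab
        else MetabolismModel()
    )
    mc_doc = doc.get("mc")
    settings = None
    if mc_doc is not None:
        occ = mc_doc.pop("occasions", {})
        settings = MCSettings(
            seed=int(mc_doc.pop("seed", 0)),
            occasions_family=occ.get("family", "fixed"),
            occasions_dispersion=occ.get("dispersion", 0.0),
            **mc_doc,
        )
    return config, curves, metabolism, settings
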