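"""Deterministic chronic and acute dietary exposure and risk characterisation.

Chronic exposure per pesticide is the national estimated daily intake

    NEDI = mean residue concentration x daily consumption / body weight

with the chronic hazard quotient HQc = NEDI / ADI.  Acute exposure uses the
IESTI Case 2a model (applicable when the edible-unit weight Ue satisfies
25 g <= Ue < large portion LP):

    IESTI = (Ue x HR x v + (LP - Ue) x HR) / bw

where HR is the highest residue found and v the unit-to-unit variability
factor.  HQa = IESTI / ARfD, falling back to the ADI when no ARfD is
established (flagged).  Hazard indices HIc and HIa sum the quotients over
detected pesticides; values below 1 are considered acceptable.

Non-detects enter the chronic mean through the censoring substitution
policies LB/MB/UB, so every chronic quantity comes in a monotone triple
LB <= MB <= UB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CensoringPolicy,
    MonitoringDataset,
    PesticideRef,
    ReferenceTable,
    mean_concentration,
)
from .errors import AnalyteLookupError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_UNIT_WEIGHT_KG = 0.0544
DEFAULT_VARIABILITY_FACTOR = 3.0


@dataclass(frozen=True)
class ExposureParams:
    """Population-specific consumption and IESTI constants.

    consumption : daily commodity consumption, kg/day
    bw : body weight, kg
    ue : unit weight of the edible portion, kg (Case 2a needs ue >= 0.025)
    v : variability factor for the composite-sample unit
    lp : large portion size, kg (Case 2a needs ue < lp)
    """

    population: str
    consumption: float
    bw: float
    lp: float
    ue: float = DEFAULT_UNIT_WEIGHT_KG
    v: float = DEFAULT_VARIABILITY_FACTOR

    def __post_init__(self) -> None:
        for label, value in (
            ("consumption", self.consumption),
            ("bw", self.bw),
            ("ue", self.ue),
            ("v", self.v),
            ("lp", self.lp),
        ):
            if not value > 0:
                raise ValidationError(f"{label} must be positive, got {value}")

    @classmethod
    def adult(cls, **overrides) -> "ExposureParams":
        """Default adult parameters: 0.0011 kg/day, 70 kg bw, LP 0.168 kg."""
        base = dict(population="adult", consumption=0.0011, bw=70.0, lp=0.168)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def child(cls, **overrides) -> "ExposureParams":
        """Default child parameters: 0.0004 kg/day, 23 kg bw, LP 0.092 kg."""
        base = dict(population="child", consumption=0.0004, bw=23.0, lp=0.092)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class HazardIndex:
    value: float
    acceptable: bool  # strict: value < 1


@dataclass
class ExposureReport:
    """Bundle of deterministic exposure outputs.

    chronic : per (analyte, population, policy): mean concentration, NEDI, HQc
    acute : per (analyte, population): HR, IESTI, HQa, ARfD-fallback flag
    hazard_indices : per (population, policy): HIc, plus HIa per population
    contributions : per (analyte, population, policy): share of HIc
    excluded : analytes skipped for lack of an ADI
    """

    chronic: pd.DataFrame
    acute: pd.DataFrame
    hazard_indices: pd.DataFrame
    contributions: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def nedi(mean_conc: float, params: ExposureParams) -> float:
    """National estimated daily intake, mg/kg bw/day."""
    if mean_conc < 0:
        raise ValidationError("mean concentration cannot be negative")
    return mean_conc * params.consumption / params.bw


def hq_chronic(nedi_value: float, adi: float) -> float:
    """Chronic hazard quotient NEDI/ADI (dimensionless)."""
    if not adi > 0:
        raise ValidationError("ADI must be positive")
    if nedi_value < 0:
        raise ValidationError("NEDI cannot be negative")
    return nedi_value / adi


def iesti_case2a(hr: float, params: ExposureParams) -> float:
    """IESTI under Case 2a, mg/kg bw.

    Requires 0.025 kg <= Ue < LP; inputs outside the applicability window
    raise rather than silently switching to another IESTI case.
    """
    if hr < 0:
        raise ValidationError("highest residue cannot be negative")
    if params.ue < 0.025:
        raise ValidationError(
            f"Case 2a requires Ue >= 0.025 kg, got Ue = {params.ue}"
        )
    if not params.ue < params.lp:
        raise ValidationError(
            f"Case 2a requires Ue < LP, got Ue = {params.ue}, LP = {params.lp}"
        )
    return (params.ue * hr * params.v + (params.lp - params.ue) * hr) / params.bw


def hq_acute(iesti: float, ref: PesticideRef) -> tuple[float, bool]:
    """Acute hazard quotient IESTI/ARfD.

    Returns ``(hq, fallback)``; when the analyte has no established ARfD the
    ADI is used conservatively and ``fallback`` is True.
    """
    if iesti < 0:
        raise ValidationError("IESTI cannot be negative")
    if ref.arfd is not None:
        return iesti / ref.arfd, False
    if ref.adi is not None:
        return iesti / ref.adi, True
    raise ValidationError(f"{ref.name}: neither ARfD nor ADI available")


def hazard_index(hqs) -> HazardIndex:
    """Hazard index: sum of hazard quotients; acceptable iff strictly < 1."""
    values = np.asarray(list(hqs), dtype=float)
    if values.size and (np.any(values < 0) or not np.all(np.isfinite(values))):
        raise ValidationError("hazard quotients must be finite and nonnegative")
    total = float(values.sum()) if values.size else 0.0
    return HazardIndex(value=total, acceptable=total < 1.0)


def scenario_report(
    dataset: MonitoringDataset,
    refs: ReferenceTable,
    params_by_population: list[ExposureParams] | None = None,
    policies: tuple[CensoringPolicy, ...] = (
        CensoringPolicy.LB,
        CensoringPolicy.MB,
        CensoringPolicy.UB,
    ),
) -> ExposureReport:
    """Full deterministic risk characterisation of a monitoring dataset.

    Chronic quantities are computed per detected pesticide under every
    censoring policy and population; acute quantities use the per-pesticide
    maximum concentration (HR).  Pesticides lacking an ADI are excluded with
    a warning rather than aborting the report.
    """
    if params_by_population is None:
        params_by_population = [ExposureParams.adult(), ExposureParams.child()]
    detected = sorted({a for s in dataset.samples for a in s.detections})
    missing_refs = [a for a in detected if a not in refs]
    if missing_refs:
        raise AnalyteLookupError(
            f"detected analytes absent from the reference table: {missing_refs}"
        )
    excluded = [a for a in detected if refs[a].adi is None]
    usable = [a for a in detected if a not in excluded]
    for analyte in excluded:
        logger.warning("excluding %s from risk characterisation: no ADI", analyte)

    chronic_rows = []
    acute_rows = []
    for analyte in usable:
        ref = refs[analyte]
        hr = max(
            (s.detections[analyte] for s in dataset.samples if analyte in s.detections),
            default=0.0,
        )
        for params in params_by_population:
            for policy in policies:
                mean_c = mean_concentration(dataset, analyte, policy, refs)
                intake = nedi(mean_c, params)
                chronic_rows.append(
                    {
                        "analyte": analyte,
                        "population": params.population,
                        "policy": policy.value,
                        "mean_concentration_mg_kg": mean_c,
                        "nedi_mg_kg_bw_day": intake,
                        "hq_chronic": hq_chronic(intake, ref.adi),
                    }
                )
            iesti = iesti_case2a(hr, params)
            hqa, fallback = hq_acute(iesti, ref)
            acute_rows.append(
                {
                    "analyte": analyte,
                    "population": params.population,
                    "hr_mg_kg": hr,
                    "iesti_mg_kg_bw": iesti,
                    "hq_acute": hqa,
                    "arfd_fallback": fallback,
                }
            )

    chronic = pd.DataFrame(
        chronic_rows,
        columns=["analyte", "population", "policy", "mean_concentration_mg_kg",
                 "nedi_mg_kg_bw_day", "hq_chronic"],
    )
    acute = pd.DataFrame(
        acute_rows,
        columns=["analyte", "population", "hr_mg_kg", "iesti_mg_kg_bw",
                 "hq_acute", "arfd_fallback"],
    )

    hi_rows = []
    contrib_rows = []
    for params in params_by_population:
        pop = params.population
        for policy in policies:
            mask = (chronic["population"] == pop) & (chronic["policy"] == policy.value)
            hqs = chronic.loc[mask, "hq_chronic"]
            hic = hazard_index(hqs)
            hi_rows.append(
                {
                    "population": pop,
                    "policy": policy.value,
                    "kind": "chronic",
                    "hi": hic.value,
                    "acceptable": hic.acceptable,
                }
            )
            if hic.value > 0:
                for analyte, hq in zip(chronic.loc[mask, "analyte"], hqs):
                    contrib_rows.append(
                        {
                            "analyte": analyte,
                            "population": pop,
                            "policy": policy.value,
                            "share_of_hic": hq / hic.value,
                        }
                    )
        hqa_values = acute.loc[acute["population"] == pop, "hq_acute"]
        hia = hazard_index(hqa_values)
        hi_rows.append(
            {
                "population": pop,
                "policy": "",
                "kind": "acute",
                "hi": hia.value,
                "acceptable": hia.acceptable,
            }
        )

    hazard_indices = pd.DataFrame(
        hi_rows, columns=["population", "policy", "kind", "hi", "acceptable"]
    )
    contributions = pd.DataFrame(
        contrib_rows, columns=["analyte", "population", "policy", "share_of_hic"]
    )
    return ExposureReport(
        chronic=chronic,
        acute=acute,
        hazard_indices=hazard_indices,
        contributions=contributions,
        excluded=excluded,
    )
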