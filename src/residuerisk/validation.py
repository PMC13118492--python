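"""Method-validation statistics for multi-residue analysis.

Implements the performance figures used to judge a residue method against
SANTE-style acceptability windows: recovery (trueness), repeatability and
within-laboratory reproducibility RSDs, LOQ from blank replicates, top-down
expanded measurement uncertainty, calibration linearity, and the retention
time / ion-ratio identification tolerances.

Conventions: sample (n-1) standard deviations; all acceptability windows are
inclusive at their boundaries (a recovery of exactly 70% or 120% passes, an
RSD of exactly 20% passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError

# SANTE-style acceptability windows (inclusive)
RECOVERY_WINDOW = (70.0, 120.0)
RSD_MAX = 20.0
RT_TOLERANCE_MIN = 0.1
ION_RATIO_TOLERANCE_PCT = 30.0
R2_MIN = 0.99
DEFAULT_COVERAGE_FACTOR = 2.0


@dataclass(frozen=True)
class FortifiedReplicateSet:
    """Replicate measurements of a blank matrix spiked at one level."""

    analyte: str
    spike_level: float
    values: tuple[float, ...]
    day: str = ""
    analyst: str = ""

    def __post_init__(self) -> None:
        if not self.values:
            raise ValidationError(f"{self.analyte}: replicate set is empty")
        if not self.spike_level > 0:
            raise ValidationError(f"{self.analyte}: spike level must be positive")


@dataclass
class ValidationReport:
    """Summary validation figures for one analyte."""

    analyte: str
    recovery_pct: float
    rsdr_pct: float
    rsdwr_pct: float
    loq: float
    expanded_uncertainty_pct: float
    r_squared: float
    coverage_factor: float = DEFAULT_COVERAGE_FACTOR
    compliant: dict[str, bool] = field(default_factory=dict)


def recovery_percent(measured_mean: float, spike_level: float) -> float:
    """Recovery as a percentage of the fortification level."""
    if not spike_level > 0:
        raise ValidationError("spike level must be positive")
    return 100.0 * measured_mean / spike_level


def rsd_percent(values) -> float:
    """Relative standard deviation (%), sample sd over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values for an RSD")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def within_lab_rsd(groups: list[FortifiedReplicateSet]) -> float:
    """Within-laboratory reproducibility RSD (%).

    Computed as the total RSD of the pooled value set across all day/analyst
    groups (not an ANOVA variance-components split), so between-group shifts
    inflate it the way a reproducibility study intends.
    """
    if not groups:
        raise ValidationError("need at least one replicate group")
    pooled = np.concatenate([np.asarray(g.values, dtype=float) for g in groups])
    return rsd_percent(pooled)


def loq_estimate(blank_replicates, expected_n: int | None = 10) -> float:
    """LOQ as 10x the sample standard deviation of fortified-blank replicates.

    ``expected_n`` enforces the protocol's replicate count (pass ``None`` to
    skip the check).  An all-equal replicate set yields 0, which callers
    should treat as "below the reporting floor" rather than a usable LOQ.
    """
    x = np.asarray(blank_replicates, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 replicates for an LOQ estimate")
    if expected_n is not None and x.size != expected_n:
        raise ValidationError(
            f"protocol requires {expected_n} replicates, got {x.size}"
        )
    return float(10.0 * x.std(ddof=1))


def expanded_uncertainty(
    bias_pct: float, rsdwr_pct: float, k: float = DEFAULT_COVERAGE_FACTOR
) -> float:
    """Expanded measurement uncertainty U (%) by the top-down route.

    The combined standard uncertainty is the root sum of squares of the bias
    and the within-laboratory reproducibility, expanded by the coverage
    factor k (k = 2 for ~95% coverage).
    """
    if not k > 0:
        raise ValidationError("coverage factor must be positive")
    return float(k * math.hypot(bias_pct, rsdwr_pct))


def linearity(levels, responses) -> float:
    """Coefficient of determination R^2 of response on concentration level."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValidationError("levels and responses must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 calibration points")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class IdentificationResult:
    rt_ok: bool
    ion_ratio_ok: bool

    @property
    def ok(self) -> bool:
        return self.rt_ok and self.ion_ratio_ok


def identification_check(
    rt_sample: float,
    rt_reference: float,
    ion_ratio_sample: float,
    ion_ratio_reference: float,
    rt_tolerance: float = RT_TOLERANCE_MIN,
    ion_ratio_tolerance_pct: float = ION_RATIO_TOLERANCE_PCT,
) -> IdentificationResult:
    """Analyte identification by retention time and ion-ratio tolerances.

    Passes when |rt deviation| <= 0.1 min and the relative ion-ratio
    deviation is <= 30% (both inclusive).
    """
    if not rt_reference > 0:
        raise ValidationError("reference retention time must be positive")
    if not ion_ratio_reference > 0:
        raise ValidationError("reference ion ratio must be positive")
    # inclusive boundaries, guarded against binary representation error so a
    # deviation of exactly the tolerance passes
    eps = 1e-9
    rt_ok = abs(rt_sample - rt_reference) <= rt_tolerance * (1 + eps)
    deviation_pct = 100.0 * abs(ion_ratio_sample - ion_ratio_reference) / ion_ratio_reference
    return IdentificationResult(
        rt_ok=rt_ok,
        ion_ratio_ok=deviation_pct <= ion_ratio_tolerance_pct * (1 + eps),
    )


def sante_compliance(report: ValidationReport) -> dict[str, bool]:
    """Per-criterion pass/fail flags against the SANTE-style windows.

    All boundaries are inclusive.  The flags are also stored on the report's
    ``compliant`` mapping.
    """
    lo, hi = RECOVERY_WINDOW
    flags = {
        "recovery": lo <= report.recovery_pct <= hi,
        "rsdr": 0.0 <= report.rsdr_pct <= RSD_MAX,
        "rsdwr": 0.0 <= report.rsdwr_pct <= RSD_MAX,
    }
    if not math.isnan(report.r_squared):
        flags["linearity"] = report.r_squared >= R2_MIN
    flags["overall"] = all(flags.values())
    report.compliant = flags
    return flags


def validate_analyte(
    groups: list[FortifiedReplicateSet],
    blank_replicates=None,
    levels=None,
    responses=None,
    k: float = DEFAULT_COVERAGE_FACTOR,
) -> ValidationReport:
    """Assemble a full :class:`ValidationReport` from replicate data.

    Recovery and RSDr come from the first (within-day) group; RSD_WR pools
    all groups; bias enters the uncertainty budget as the mean absolute
    deviation of recovery from 100%.
    """
    if not groups:
        raise ValidationError("need at least one replicate group")
    analyte = groups[0].analyte
    first = groups[0]
    rec = recovery_percent(float(np.mean(first.values)), first.spike_level)
    rsdr = rsd_percent(first.values)
    rsdwr = within_lab_rsd(groups)
    recoveries = [
        recovery_percent(float(np.mean(g.values)), g.spike_level) for g in groups
    ]
    bias = float(np.mean([abs(r - 100.0) for r in recoveries]))
    u = expanded_uncertainty(bias, rsdwr, k)
    loq = loq_estimate(blank_replicates, expected_n=None) if blank_replicates is not None else float("nan")
    r2 = linearity(levels, responses) if levels is not None and responses is not None else float("nan")
    report = ValidationReport(
        analyte=analyte,
        recovery_pct=rec,
        rsdr_pct=rsdr,
        rsdwr_pct=rsdwr,
        loq=loq,
        expanded_uncertainty_pct=u,
        r_squared=r2,
        coverage_factor=k,
    )
    sante_compliance(report)
    return report
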