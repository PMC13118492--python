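"""Matrix-based risk ranking of pesticides.

A composite score per pesticide combines six components in the style of the
UK Veterinary Residues Committee prioritisation matrix:

* A — acute toxicity (from the LD50),
* B — toxic potency (from the ADI),
* C — dietary contribution of the commodity,
* D — application frequency (frequency of dosing, FOD),
* E — vulnerable-population exposure (defaults to 3 when evidence is
  insufficient),
* F — residue levels relative to the MRL (a weighted mean over the sample
  distribution, between 1 and 4).

The composite score is S = (A + B) x (C + D + E) x F, and pesticides are
classed high (S >= 20), medium (15 <= S < 20) or low (S < 15) risk.  The
grouping of the product is configurable because variants of the matrix
exist.  Pesticides without an established ADI are excluded from scoring.

The default scoring bands for A-D are documented reconstructions of the
matrix's published intent (order-of-magnitude cut-points), not a transcription
of any appendix; they live in :data:`DEFAULT_BANDS` and are user-editable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import ValidationError

#: Largest admissible integer for any component score.
MAX_COMPONENT = 5

#: Reconstructed default scoring bands.  Each entry maps a component to a
#: list of (upper_bound, score) pairs scanned in order; the first band whose
#: bound contains the value assigns the score.
DEFAULT_BANDS = {
    # A: acute toxicity from oral LD50 (mg/kg bw); lower LD50 = more toxic.
    "A": [(20.0, 4), (200.0, 3), (2000.0, 2), (float("inf"), 1)],
    # B: toxic potency from ADI (mg/kg bw/day); lower ADI = more potent.
    "B": [(0.001, 4), (0.01, 3), (0.1, 2), (float("inf"), 1)],
    # C: dietary contribution of the commodity (% of diet).
    "C": [(2.5, 1), (10.0, 2), (25.0, 3), (float("inf"), 4)],
    # D: frequency of dosing FOD (% of growth days treated).
    "D": [(1.0, 1), (5.0, 2), (10.0, 3), (float("inf"), 4)],
}


@dataclass(frozen=True)
class RiskComponents:
    """Integer component scores A-E of the ranking matrix."""

    a: int
    b: int
    c: int
    d: int
    e: int = 3

    def __post_init__(self) -> None:
        for label, value in zip("abcde", (self.a, self.b, self.c, self.d, self.e)):
            if not isinstance(value, int) or not 1 <= value <= MAX_COMPONENT:
                raise ValidationError(
                    f"component {label.upper()} must be an integer in "
                    f"[1, {MAX_COMPONENT}], got {value!r}"
                )


@dataclass(frozen=True)
class FodInput:
    """Application count and crop growth period for the FOD."""

    n_applications: int
    growth_period_days: float

    def __post_init__(self) -> None:
        if self.n_applications < 0:
            raise ValidationError("number of applications cannot be negative")
        if not self.growth_period_days > 0:
            raise ValidationError("growth period must be positive")


@dataclass(frozen=True)
class FScoreInput:
    """Sample counts by residue band for the residue-level score F.

    ``f0``: no quantified residue; ``f1``: residue below the MRL;
    ``f2``: between 1x and 10x MRL (inclusive); ``f3``: above 10x MRL;
    ``n``: total samples.
    """

    f0: int
    f1: int
    f2: int
    f3: int
    n: int

    def __post_init__(self) -> None:
        parts = (self.f0, self.f1, self.f2, self.f3)
        if any(p < 0 for p in parts) or self.n <= 0:
            raise ValidationError("band counts must be nonnegative and n positive")
        if sum(parts) != self.n:
            raise ValidationError(
                f"band counts sum to {sum(parts)}, expected n = {self.n}"
            )


@dataclass(frozen=True)
class RiskScore:
    s: float
    category: str


def band_score(value: float, bands) -> int:
    """Score a value against ordered (upper_bound, score) bands."""
    for bound, score in bands:
        if value <= bound:
            return score
    raise ValidationError(f"no band covers value {value}")


def frequency_of_dosing(inp: FodInput) -> float:
    """FOD (%): applications per crop growth day, times 100."""
    return 100.0 * inp.n_applications / inp.growth_period_days


def residue_level_score(inp: FScoreInput) -> float:
    """Residue-level score F in [1, 4]: weighted mean of band weights 1-4."""
    return (inp.f0 * 1 + inp.f1 * 2 + inp.f2 * 3 + inp.f3 * 4) / inp.n


def risk_category(s: float) -> str:
    """high for S >= 20, medium for 15 <= S < 20, low for S < 15."""
    if s < 0:
        raise ValidationError("risk score cannot be negative")
    if s >= 20:
        return "high"
    if s >= 15:
        return "medium"
    return "low"


def _vrc_grouping(components: RiskComponents, f: float) -> float:
    return (components.a + components.b) * (components.c + components.d + components.e) * f


def composite_score(
    components: RiskComponents,
    f: float,
    grouping: Callable[[RiskComponents, float], float] = _vrc_grouping,
) -> RiskScore:
    """Composite matrix score S with its risk category.

    The default grouping is (A + B) x (C + D + E) x F; pass another callable
    to evaluate a different arrangement of the same components.
    """
    if not 1.0 <= f <= 4.0:
        raise ValidationError(f"residue-level score F must lie in [1, 4], got {f}")
    s = float(grouping(components, f))
    return RiskScore(s=s, category=risk_category(s))


def f_bands_from_concentrations(concentrations, mrl: float, n_total: int) -> FScoreInput:
    """Bin detected concentrations into the F bands for ``n_total`` samples.

    ``concentrations`` holds only the quantified residues of one analyte;
    the remaining ``n_total - len(concentrations)`` samples count as band 0.
    The F2 band is inclusive at both MRL and 10x MRL; F3 is strictly above
    10x MRL.
    """
    if not mrl > 0:
        raise ValidationError("MRL must be positive")
    concs = list(concentrations)
    if len(concs) > n_total:
        raise ValidationError("more detections than samples")
    f1 = sum(1 for c in concs if c < mrl)
    f2 = sum(1 for c in concs if mrl <= c <= 10 * mrl)
    f3 = sum(1 for c in concs if c > 10 * mrl)
    return FScoreInput(f0=n_total - len(concs), f1=f1, f2=f2, f3=f3, n=n_total)
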