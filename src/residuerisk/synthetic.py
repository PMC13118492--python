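"""Synthetic residue-monitoring data with survey-like occurrence structure.

The generator emulates a multi-residue monitoring survey: each analyte has a
per-sample detection probability and a right-skewed concentration law — a
log-normal truncated to the printed min/max range of the survey summary.
Multi-residue co-occurrence (several residues in one sample, with a heavy
tail) is produced by a per-sample latent gamma "contamination propensity"
that multiplies the detection odds of every analyte; base odds are calibrated
numerically so the marginal detection frequency still equals ``p_detect``.

Sampling is inverse-CDF throughout, so a dataset is a pure function of the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import MonitoringDataset, PesticideRef, ReferenceTable, SampleRecord
from .errors import ValidationError

__all__ = [
    "OccurrenceSpec",
    "CooccurrenceModel",
    "build_spec_from_summary",
    "generate_dataset",
    "truncated_lognormal_mean",
    "default_survey_specs",
    "synthetic_reference_table",
    "PROVINCE_SIZES",
    "SURVEY_SUMMARIES",
]

#: Per-province sample counts of the emulated gherkin survey.
PROVINCE_SIZES: dict[str, int] = {
    "Afyonkarahisar": 280,
    "Balikesir": 104,
    "Izmir": 152,
    "Manisa": 214,
    "Mardin": 155,
}

#: Survey summary per analyte: (detection frequency, min, mean, max) in mg/kg.
#: Means marked None were not reported for the rarer analytes; the builder
#: then assumes the geometric midpoint of the range (right-skewed data).
SURVEY_SUMMARIES: dict[str, tuple[float, float, float | None, float]] = {
    "flonicamid": (0.362, 0.013, 0.048, 0.382),
    "propamocarb": (0.275, 0.015, 0.056, 1.030),
    "acetamiprid": (0.133, 0.015, 0.040, 0.331),
    "azoxystrobin": (0.112, 0.011, 0.038, 0.447),
    "ametoctradin": (0.088, 0.013, None, 0.570),
    "fluopyram": (0.037, 0.015, None, 0.160),
    "spiromesifen": (0.037, 0.015, None, 0.110),
    "dimethomorph": (0.034, 0.015, None, 0.230),
    "metalaxyl": (0.029, 0.012, None, 0.343),
    "fluopicolide": (0.025, 0.015, None, 0.130),
    "pyridaben": (0.023, 0.015, None, 0.150),
    "famoxadone": (0.021, 0.011, None, 0.084),
    "clofentezine": (0.016, 0.015, None, 0.250),
    "boscalid": (0.014, 0.016, None, 0.106),
    "tebuconazole": (0.010, 0.015, None, 0.077),
}


@dataclass(frozen=True)
class OccurrenceSpec:
    """Occurrence law for one analyte.

    ``p_detect`` is the marginal probability that a sample carries a
    quantified residue of the analyte; detected concentrations follow a
    log-normal with parameters (``mu``, ``sigma``) on the log scale,
    truncated to ``[lower, upper]`` mg/kg.  ``province_multipliers``
    optionally scale the detection odds per region.
    """

    analyte: str
    p_detect: float
    mu: float
    sigma: float
    lower: float
    upper: float
    province_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValidationError(f"{self.analyte}: p_detect must be in [0, 1]")
        if self.sigma < 0:
            raise ValidationError(f"{self.analyte}: sigma must be nonnegative")
        if not (0 < self.lower <= self.upper):
            raise ValidationError(f"{self.analyte}: need 0 < lower <= upper")

    def truncated_mean(self) -> float:
        return truncated_lognormal_mean(self.mu, self.sigma, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw detected concentrations by inverse CDF on the truncated law."""
        if size == 0:
            return np.zeros(0)
        if self.sigma == 0 or self.lower == self.upper:
            return np.full(size, min(max(math.exp(self.mu), self.lower), self.upper))
        a = (math.log(self.lower) - self.mu) / self.sigma
        b = (math.log(self.upper) - self.mu) / self.sigma
        fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
        u = fa + (fb - fa) * rng.random(size)
        z = stats.norm.ppf(u)
        return np.exp(self.mu + self.sigma * z)


@dataclass(frozen=True)
class CooccurrenceModel:
    """Latent-propensity model for multi-residue co-occurrence.

    Each sample draws a gamma-distributed contamination propensity with mean
    1 and variance ``dispersion``; the propensity multiplies every analyte's
    detection odds.  ``dispersion = 0`` reproduces independent detections.
    """

    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")


def truncated_lognormal_mean(
    mu: float, sigma: float, lower: float, upper: float
) -> float:
    """Mean of a log-normal(mu, sigma) truncated to [lower, upper]."""
    if sigma == 0 or lower == upper:
        return min(max(math.exp(mu), lower), upper)
    a = (math.log(lower) - mu) / sigma
    b = (math.log(upper) - mu) / sigma
    den = stats.norm.cdf(b) - stats.norm.cdf(a)
    if den <= 0:
        # support numerically outside the truncation window; fall back to the
        # nearer bound
        return lower if math.exp(mu) < lower else upper
    num = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
    return math.exp(mu + 0.5 * sigma**2) * num / den


def build_spec_from_summary(
    analyte: str,
    p_detect: float,
    cmin: float,
    cmean: float,
    cmax: float,
    loq: float,
    sigma: float | None = None,
    province_multipliers: dict[str, float] | None = None,
) -> OccurrenceSpec:
    """Turn printed survey summary statistics into an :class:`OccurrenceSpec`.

    The log-scale spread ``sigma`` defaults to ``log(cmax/cmin)/4`` (the range
    spans roughly four standard deviations); the location ``mu`` is then
    solved numerically so the truncated mean matches ``cmean`` (within 5%,
    checked).
    """
    if not (loq <= cmin <= cmean <= cmax):
        raise ValidationError(
            f"{analyte}: need loq <= cmin <= cmean <= cmax, got "
            f"({loq}, {cmin}, {cmean}, {cmax})"
        )
    if cmin == cmax:
        return OccurrenceSpec(analyte, p_detect, math.log(cmin), 0.0, cmin, cmax,
                              province_multipliers)
    if sigma is None:
        sigma = math.log(cmax / cmin) / 4.0
    lo = math.log(cmin) - 5.0 * sigma
    hi = math.log(cmax) + 5.0 * sigma

    def gap(mu: float) -> float:
        return truncated_lognormal_mean(mu, sigma, cmin, cmax) - cmean

    if gap(lo) * gap(hi) <= 0:
        mu = optimize.brentq(gap, lo, hi, xtol=1e-12)
    else:
        # target mean at (or numerically beyond) a truncation bound
        mu = lo if abs(gap(lo)) < abs(gap(hi)) else hi
    spec = OccurrenceSpec(analyte, p_detect, mu, sigma, cmin, cmax,
                          province_multipliers)
    achieved = spec.truncated_mean()
    if abs(achieved - cmean) > 0.05 * cmean:
        raise ValidationError(
            f"{analyte}: cannot match mean {cmean} within 5% "
            f"(achieved {achieved:.4g}); adjust sigma"
        )
    return spec


def _calibrate_base_odds(p_detect: float, dispersion: float) -> float:
    """Base odds o such that E_t[o*t / (1 + o*t)] = p_detect for gamma t.

    t has mean 1 and variance ``dispersion``; the expectation is evaluated on
    gamma quantile midpoints, and o solved by bisection.
    """
    if p_detect <= 0.0:
        return 0.0
    if p_detect >= 1.0:
        return math.inf
    if dispersion == 0:
        return p_detect / (1.0 - p_detect)
    shape = 1.0 / dispersion
    k = 2001
    t = stats.gamma.ppf((np.arange(k) + 0.5) / k, a=shape, scale=dispersion)

    def marginal(log_o: float) -> float:
        ot = math.exp(log_o) * t
        return float(np.mean(ot / (1.0 + ot))) - p_detect

    return math.exp(optimize.brentq(marginal, -30.0, 30.0, xtol=1e-10))


def generate_dataset(
    specs: list[OccurrenceSpec],
    province_sizes: dict[str, int],
    cooc: CooccurrenceModel | None = None,
    seed: int = 0,
) -> MonitoringDataset:
    """Generate a reproducible synthetic monitoring dataset.

    One sample per roster slot; per sample a latent propensity multiplies
    every analyte's detection odds (see :class:`CooccurrenceModel`), detection
    is Bernoulli, and concentrations come from the analyte's truncated
    log-normal.  All randomness flows from a single ``numpy`` generator
    seeded with ``seed``.
    """
    if not specs:
        raise ValidationError("need at least one occurrence spec")
    names = [s.analyte for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate analytes in spec list")
    for prov, n in province_sizes.items():
        if n <= 0:
            raise ValidationError(f"province {prov!r}: sample count must be positive")
    cooc = cooc or CooccurrenceModel()
    rng = np.random.default_rng(seed)

    provinces = [p for p, n in province_sizes.items() for _ in range(n)]
    n_total = len(provinces)
    if cooc.dispersion > 0:
        propensity = rng.gamma(shape=1.0 / cooc.dispersion,
                               scale=cooc.dispersion, size=n_total)
    else:
        propensity = np.ones(n_total)

    width = max(4, len(str(n_total)))
    samples = [
        SampleRecord(sample_id=f"S{i + 1:0{width}d}", province=prov)
        for i, prov in enumerate(provinces)
    ]
    for spec in specs:
        base_odds = _calibrate_base_odds(spec.p_detect, cooc.dispersion)
        mult = np.array(
            [
                (spec.province_multipliers or {}).get(p, 1.0)
                for p in provinces
            ]
        )
        odds = base_odds * propensity * mult
        with np.errstate(invalid="ignore"):
            p = np.where(np.isinf(odds), 1.0, odds / (1.0 + odds))
        detected = rng.random(n_total) < p
        concs = spec.sample(rng, int(detected.sum()))
        for idx, conc in zip(np.flatnonzero(detected), concs):
            samples[idx].detections[spec.analyte] = float(conc)

    return MonitoringDataset(samples=samples, panel=list(names),
                             provinces=dict(province_sizes))


def default_survey_specs(loq: float = 0.01) -> list[OccurrenceSpec]:
    """Occurrence specs reproducing the emulated survey's printed summaries.

    Analytes whose mean concentration was not reported get the geometric
    midpoint of their min/max range as the assumed mean.
    """
    specs = []
    for analyte, (p, cmin, cmean, cmax) in SURVEY_SUMMARIES.items():
        if cmean is None:
            cmean = math.sqrt(cmin * cmax)
        specs.append(build_spec_from_summary(analyte, p, cmin, cmean, cmax,
                                             loq=min(loq, cmin)))
    return specs


def synthetic_reference_table(loq: float = 0.01) -> ReferenceTable:
    """Synthetic regulatory constants for the default survey panel.

    The MRL/ADI/ARfD values here are plausible stand-ins for demonstration
    and testing, NOT regulatory data; real assessments must supply a
    reference table from the applicable pesticide database.
    """
    rows = [
        # name, class, authorised, mrl, adi, arfd (None = not established)
        ("flonicamid", "insecticide", True, 0.5, 0.025, 0.025),
        ("propamocarb", "fungicide", True, 5.0, 0.29, 1.0),
        ("acetamiprid", "insecticide", True, 0.3, 0.025, 0.025),
        ("azoxystrobin", "fungicide", True, 1.0, 0.2, None),
        ("ametoctradin", "fungicide", True, 2.0, 10.0, None),
        ("fluopyram", "fungicide", True, 0.5, 0.012, 0.5),
        ("spiromesifen", "insecticide", False, 0.02, 0.03, 2.0),
        ("dimethomorph", "fungicide", False, 0.01, 0.05, 0.6),
        ("metalaxyl", "fungicide", True, 0.01, 0.08, 0.5),
        ("fluopicolide", "fungicide", True, 0.5, 0.08, 0.6),
        ("pyridaben", "acaricide", True, 0.15, 0.01, 0.05),
        ("famoxadone", "fungicide", False, 0.01, 0.006, 0.1),
        ("clofentezine", "acaricide", False, 0.02, 0.02, None),
        ("boscalid", "fungicide", True, 3.0, 0.04, None),
        ("tebuconazole", "fungicide", True, 0.6, 0.03, 0.03),
    ]
    return ReferenceTable(
        PesticideRef(name=n, pclass=c, authorised=a, mrl=m, adi=adi,
                     arfd=arfd, loq=loq)
        for n, c, a, m, adi, arfd in rows
    )
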