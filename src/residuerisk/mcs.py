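"""Probabilistic chronic risk characterisation by Monte Carlo simulation.

Residue concentrations and daily consumption are modelled as log-normal
(right-skewed), body weight as a normal truncated to positive values.  Each
iteration draws all inputs jointly (independently across pesticides and
between concentration, consumption and body weight) and evaluates the
chronic hazard index

    HIc = sum_p (conc_p x consumption / bw) / ADI_p .

Outputs are the HIc summary (mean, median, 5th/95th percentiles), the
probability of exceeding unity, per-pesticide ADI-exceedance probabilities,
and a contribution-to-variance sensitivity analysis based on signed squared
Spearman rank correlations (a standardized-regression-coefficient variant is
available behind a switch).

All randomness flows from one seeded numpy PCG64 generator, so a result is a
pure function of (spec, config).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CensoringPolicy, MonitoringDataset, ReferenceTable, substitute_censored
from .errors import ValidationError
from .exposure import ExposureParams

DEFAULT_ITERATIONS = 10_000
DEFAULT_CONSUMPTION_CV = 0.30
DEFAULT_BW_CV = 0.15


@dataclass(frozen=True)
class LogNormalParams:
    """Log-scale location and spread of a log-normal variable."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")

    @classmethod
    def from_mean_cv(cls, mean: float, cv: float) -> "LogNormalParams":
        """Parameters matching an arithmetic mean and coefficient of variation."""
        if not mean > 0 or cv < 0:
            raise ValidationError("need mean > 0 and cv >= 0")
        sigma2 = math.log1p(cv * cv)
        return cls(mu=math.log(mean) - 0.5 * sigma2, sigma=math.sqrt(sigma2))

    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)


@dataclass(frozen=True)
class NormalParams:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")


@dataclass(frozen=True)
class DistributionSpec:
    """Distributional assumptions feeding the simulation."""

    residues: dict[str, LogNormalParams]
    consumption: LogNormalParams
    bw: NormalParams


@dataclass(frozen=True)
class MCSConfig:
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    population: str = "adult"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


@dataclass
class MCSResult:
    """Monte Carlo output: HIc summary plus raw draws for sensitivity."""

    mean: float
    median: float
    p5: float
    p95: float
    prob_exceed_unity: float
    adi_exceedance: dict[str, float]
    hi_samples: np.ndarray
    inputs: pd.DataFrame
    config: MCSConfig


@dataclass(frozen=True)
class SensitivityResult:
    """Signed contribution-to-variance per input (%), absolute sum 100."""

    contributions: pd.DataFrame  # input, contribution_pct, rank


def fit_distributions(
    dataset: MonitoringDataset,
    refs: ReferenceTable,
    policy: CensoringPolicy,
    floor: float | None = None,
    analytes: list[str] | None = None,
) -> dict[str, LogNormalParams]:
    """Fit per-pesticide log-normal laws by method of moments.

    Moments are taken on the censoring-substituted concentration vectors of
    the ``analytes`` requested (default: every analyte with at least one
    detection).  Under LB the substituted zeros cannot enter a log-normal;
    they are floored at ``floor`` (default: half the smallest positive LOQ
    in the panel) before fitting, and an all-zero vector raises with a hint
    to use MB or UB.
    """
    if analytes is None:
        analytes = sorted({a for s in dataset.samples for a in s.detections})
    if floor is None:
        loqs = [refs[a].loq for a in analytes if a in refs]
        floor = 0.5 * min(loqs) if loqs else 1e-6
    out: dict[str, LogNormalParams] = {}
    for analyte in analytes:
        values = substitute_censored(dataset, analyte, policy, refs)
        if values.size < 2:
            raise ValidationError(f"{analyte}: need >= 2 values to fit a distribution")
        if np.all(values == 0):
            raise ValidationError(
                f"{analyte}: all-zero LB vector cannot be fitted; use MB or UB"
            )
        values = np.maximum(values, floor)
        m = float(values.mean())
        v = float(values.var(ddof=1))
        if v == 0:
            out[analyte] = LogNormalParams(mu=math.log(m), sigma=0.0)
            continue
        sigma2 = math.log1p(v / (m * m))
        out[analyte] = LogNormalParams(mu=math.log(m) - 0.5 * sigma2,
                                       sigma=math.sqrt(sigma2))
    return out


def build_spec(
    dataset: MonitoringDataset,
    refs: ReferenceTable,
    policy: CensoringPolicy,
    params: ExposureParams,
    consumption_cv: float = DEFAULT_CONSUMPTION_CV,
    bw_cv: float = DEFAULT_BW_CV,
    floor: float | None = None,
) -> DistributionSpec:
    """Assemble a :class:`DistributionSpec` from data plus population params.

    Point consumption and body-weight values are widened into distributions
    with the given coefficients of variation (defaults 30% and 15%), the
    typical spreads assumed for dietary surveys when only means are known.
    Pesticides without an ADI are dropped here, mirroring the deterministic
    exclusion.
    """
    residues = fit_distributions(dataset, refs, policy, floor=floor)
    residues = {a: p for a, p in residues.items() if refs[a].adi is not None}
    if not residues:
        raise ValidationError("no pesticide with an ADI to simulate")
    return DistributionSpec(
        residues=residues,
        consumption=LogNormalParams.from_mean_cv(params.consumption, consumption_cv),
        bw=NormalParams(mean=params.bw, sd=bw_cv * params.bw),
    )


def _draw_lognormal(rng: np.random.Generator, p: LogNormalParams, n: int) -> np.ndarray:
    if p.sigma == 0:
        return np.full(n, math.exp(p.mu))
    return np.exp(rng.normal(p.mu, p.sigma, size=n))


def _draw_positive_normal(rng: np.random.Generator, p: NormalParams, n: int) -> np.ndarray:
    """Normal draws truncated to > 0 by resampling (never clipped)."""
    if p.sd == 0:
        if not p.mean > 0:
            raise ValidationError("degenerate body weight must be positive")
        return np.full(n, p.mean)
    x = rng.normal(p.mean, p.sd, size=n)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(p.mean, p.sd, size=int(bad.sum()))
        bad = x <= 0
    return x


def run_mcs(
    spec: DistributionSpec, refs: ReferenceTable, config: MCSConfig
) -> MCSResult:
    """Run the chronic hazard-index simulation.

    Per iteration: one concentration draw per pesticide, one consumption and
    one body-weight draw shared across pesticides.  The per-pesticide ADI
    exceedance probability is P(HQ_p > 1).
    """
    rng = np.random.default_rng(config.seed)
    n = config.iterations
    inputs: dict[str, np.ndarray] = {}
    for analyte in spec.residues:
        inputs[f"conc:{analyte}"] = _draw_lognormal(rng, spec.residues[analyte], n)
    consumption = _draw_lognormal(rng, spec.consumption, n)
    bw = _draw_positive_normal(rng, spec.bw, n)
    inputs["consumption"] = consumption
    inputs["body_weight"] = bw

    hi = np.zeros(n)
    adi_exceedance: dict[str, float] = {}
    for analyte, law in spec.residues.items():
        adi = refs[analyte].adi
        if adi is None:
            raise ValidationError(f"{analyte}: cannot simulate without an ADI")
        hq = inputs[f"conc:{analyte}"] * consumption / bw / adi
        adi_exceedance[analyte] = float(np.mean(hq > 1.0))
        hi += hq

    frame = pd.DataFrame(inputs)
    p5, median, p95 = np.percentile(hi, [5, 50, 95])
    return MCSResult(
        mean=float(hi.mean()),
        median=float(median),
        p5=float(p5),
        p95=float(p95),
        prob_exceed_unity=float(np.mean(hi > 1.0)),
        adi_exceedance=adi_exceedance,
        hi_samples=hi,
        inputs=frame,
        config=config,
    )


def sensitivity_analysis(
    inputs: pd.DataFrame, hi_samples: np.ndarray, method: str = "spearman"
) -> SensitivityResult:
    """Contribution-to-variance of each input to the hazard index.

    ``spearman`` (default): signed squared Spearman rank correlation between
    each input and HIc, normalised so absolute contributions sum to 100%.
    ``src``: standardized (rank-free) regression coefficients, squared and
    signed, normalised the same way.  Zero-variance inputs contribute 0 with
    a warning.
    """
    hi = np.asarray(hi_samples, dtype=float)
    if len(inputs) != hi.size:
        raise ValidationError("inputs and hi_samples must align by iteration")
    raw: dict[str, float] = {}
    for col in inputs.columns:
        x = inputs[col].to_numpy()
        if x.std() == 0 or hi.std() == 0:
            warnings.warn(f"input {col!r} (or the output) has zero variance; "
                          "contribution set to 0")
            raw[col] = 0.0
            continue
        if method == "spearman":
            rho = stats.spearmanr(x, hi).statistic
        elif method == "src":
            rho = float(np.corrcoef((x - x.mean()) / x.std(),
                                    (hi - hi.mean()) / hi.std())[0, 1])
        else:
            raise ValidationError(f"unknown sensitivity method: {method!r}")
        raw[col] = float(np.sign(rho) * rho * rho)
    total = sum(abs(v) for v in raw.values())
    scale = 100.0 / total if total > 0 else 0.0
    frame = pd.DataFrame(
        {
            "input": list(raw),
            "contribution_pct": [v * scale for v in raw.values()],
        }
    )
    frame["rank"] = (
        frame["contribution_pct"].abs().rank(ascending=False, method="first").astype(int)
    )
    frame = frame.sort_values("rank", ignore_index=True)
    return SensitivityResult(contributions=frame)
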