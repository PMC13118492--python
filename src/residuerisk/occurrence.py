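"""Prevalence, multi-residue, MRL-exceedance and homogeneity statistics.

These are the descriptive statistics of a monitoring survey: how many
samples carry quantifiable residues, how residue counts per sample are
distributed, how often the maximum residue level (MRL) is exceeded, and
whether detection or exceedance rates differ between production regions
(Pearson chi-square homogeneity test on the 2 x k success/failure table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MonitoringDataset, ReferenceTable
from .errors import AnalyteLookupError, ValidationError

OVERALL = "overall"


@dataclass(frozen=True)
class Chi2Result:
    """Pearson chi-square homogeneity test result."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ExceedanceReport:
    """Per-detection exceedance flags plus per-province sample counts."""

    detections: pd.DataFrame  # sample_id, province, analyte, concentration, mrl, exceeds
    by_province: pd.Series  # province -> number of samples with >= 1 exceedance

    @property
    def n_exceeding_samples(self) -> int:
        return int(self.by_province.sum())


def prevalence_summary(
    dataset: MonitoringDataset, refs: ReferenceTable
) -> pd.DataFrame:
    """Per-province and overall prevalence table.

    Columns: ``n_samples``, ``n_contaminated`` (>= 1 quantified residue),
    ``detection_rate``, ``n_distinct_residues``, ``n_unauthorised`` (distinct
    detected analytes flagged unauthorised), ``n_exceeding_mrl`` (samples
    with at least one residue above its MRL).
    """
    if dataset.n_samples == 0:
        raise ValidationError("prevalence summary requires a nonempty dataset")
    exc = exceedance_table(dataset, refs)
    rows = {}
    strata = list(dataset.provinces) + [OVERALL]
    for stratum in strata:
        samples = (
            dataset.samples
            if stratum == OVERALL
            else [s for s in dataset.samples if s.province == stratum]
        )
        contaminated = [s for s in samples if s.detections]
        detected_analytes = {a for s in samples for a in s.detections}
        unauthorised = {a for a in detected_analytes if not refs[a].authorised}
        if stratum == OVERALL:
            n_exceeding = exc.n_exceeding_samples
        else:
            n_exceeding = int(exc.by_province.get(stratum, 0))
        rows[stratum] = {
            "n_samples": len(samples),
            "n_contaminated": len(contaminated),
            "detection_rate": len(contaminated) / len(samples) if samples else 0.0,
            "n_distinct_residues": len(detected_analytes),
            "n_unauthorised": len(unauthorised),
            "n_exceeding_mrl": n_exceeding,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "province"
    return out


def multi_residue_distribution(dataset: MonitoringDataset) -> pd.Series:
    """Histogram: number of residues per sample -> number of samples.

    Bin 0 counts residue-free samples; every intermediate count up to the
    maximum is present (possibly zero), and the histogram sums to the number
    of samples.
    """
    counts = [s.n_residues for s in dataset.samples]
    if not counts:
        return pd.Series(dtype=int, name="n_samples").rename_axis("n_residues")
    values = np.bincount(counts)
    return pd.Series(
        values, index=pd.RangeIndex(len(values), name="n_residues"), name="n_samples"
    )


def exceedance_table(
    dataset: MonitoringDataset, refs: ReferenceTable
) -> ExceedanceReport:
    """Flag each detection against its MRL (strict inequality).

    A residue exactly at the MRL is compliant; a sample exceeds when any of
    its residues does.  Analytes without an MRL entry raise, naming the
    analyte.
    """
    records = []
    exceeding_by_prov: dict[str, set[str]] = {p: set() for p in dataset.provinces}
    for s in dataset.samples:
        for analyte, conc in sorted(s.detections.items()):
            if analyte not in refs:
                raise AnalyteLookupError(f"no MRL available for analyte: {analyte}")
            mrl = refs[analyte].mrl
            exceeds = conc > mrl
            if exceeds:
                exceeding_by_prov.setdefault(s.province, set()).add(s.sample_id)
            records.append(
                {
                    "sample_id": s.sample_id,
                    "province": s.province,
                    "analyte": analyte,
                    "concentration_mg_kg": conc,
                    "mrl_mg_kg": mrl,
                    "exceeds": exceeds,
                }
            )
    detections = pd.DataFrame(
        records,
        columns=["sample_id", "province", "analyte", "concentration_mg_kg",
                 "mrl_mg_kg", "exceeds"],
    )
    by_province = pd.Series(
        {p: len(ids) for p, ids in exceeding_by_prov.items()}, dtype=int,
        name="n_exceeding_samples",
    ).rename_axis("province")
    return ExceedanceReport(detections=detections, by_province=by_province)


def chi2_homogeneity(successes, totals) -> Chi2Result:
    """Pearson chi-square test of equal proportions across k groups.

    The 2 x k table (successes / failures per group) is tested without
    continuity correction; df = k - 1.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if s.shape != t.shape or s.ndim != 1 or s.size < 2:
        raise ValidationError("need equal-length vectors with at least 2 groups")
    if np.any(t <= 0):
        raise ValidationError("group totals must be positive")
    if np.any(s < 0) or np.any(s > t):
        raise ValidationError("successes must satisfy 0 <= successes <= totals")
    observed = np.vstack([s, t - s])
    col = observed.sum(axis=0)
    row = observed.sum(axis=1)
    expected = np.outer(row, col) / observed.sum()
    if np.any(expected == 0):
        # one margin is empty: all groups share proportion 0 or 1
        return Chi2Result(statistic=0.0, df=int(s.size - 1), p_value=1.0)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = int(s.size - 1)
    return Chi2Result(statistic=statistic, df=df,
                      p_value=float(stats.chi2.sf(statistic, df)))
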