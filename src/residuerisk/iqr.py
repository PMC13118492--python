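"""Index of Quality for Residues (IqR).

The IqR of a sample is the sum over its quantified residues of the ratio of
the measured concentration to the analyte's maximum residue level (MRL).  It
aggregates multi-residue contamination into a single number: a sample may be
fully MRL-compliant residue-by-residue and still score poorly when many
residues co-occur.

Samples are classified as excellent (IqR = 0, residue-free), good
(0 < IqR <= 0.6), acceptable (0.6 < IqR <= 1.0; also called "adequate") or
unacceptable (IqR > 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import MonitoringDataset, ReferenceTable, SampleRecord
from .errors import AnalyteLookupError, ValidationError

CATEGORIES = ("excellent", "good", "acceptable", "unacceptable")

#: "adequate" appears as a synonym for the (0.6, 1.0] band in parts of the
#: literature; it is accepted as an alias.
CATEGORY_ALIASES = {"adequate": "acceptable"}


@dataclass(frozen=True)
class IqRResult:
    """IqR of one sample with its per-analyte contributions."""

    sample_id: str
    iqr: float
    contributions: dict[str, float]
    category: str


def iqr_category(iqr: float) -> str:
    """Quality category for an IqR value (boundaries 0.6 and 1.0 inclusive
    to the lower category)."""
    if iqr < 0:
        raise ValidationError("IqR cannot be negative")
    if iqr == 0:
        return "excellent"
    if iqr <= 0.6:
        return "good"
    if iqr <= 1.0:
        return "acceptable"
    return "unacceptable"


def iqr_value(sample: SampleRecord, refs: ReferenceTable) -> IqRResult:
    """IqR of a sample: sum of concentration/MRL over its quantified residues.

    Non-detects contribute nothing; a residue-free sample scores 0.
    """
    contributions: dict[str, float] = {}
    for analyte, conc in sorted(sample.detections.items()):
        if analyte not in refs:
            raise AnalyteLookupError(f"no MRL available for analyte: {analyte}")
        contributions[analyte] = conc / refs[analyte].mrl
    total = sum(contributions.values())
    return IqRResult(
        sample_id=sample.sample_id,
        iqr=total,
        contributions=contributions,
        category=iqr_category(total),
    )


def quality_profile(
    dataset: MonitoringDataset, refs: ReferenceTable
) -> pd.DataFrame:
    """Category proportions per province and overall.

    Rows are strata (each province plus ``overall``), columns the four
    categories; each row sums to 1.  The excellent proportion equals the
    residue-free proportion by construction.
    """
    if dataset.n_samples == 0:
        raise ValidationError("quality profile requires a nonempty dataset")
    results = {s.sample_id: iqr_value(s, refs) for s in dataset.samples}
    strata = list(dataset.provinces) + ["overall"]
    rows = {}
    for stratum in strata:
        samples = (
            dataset.samples
            if stratum == "overall"
            else [s for s in dataset.samples if s.province == stratum]
        )
        n = len(samples)
        counts = {c: 0 for c in CATEGORIES}
        for s in samples:
            counts[results[s.sample_id].category] += 1
        rows[stratum] = {c: counts[c] / n if n else 0.0 for c in CATEGORIES}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    out.index.name = "province"
    return out


def iqr_table(dataset: MonitoringDataset, refs: ReferenceTable) -> pd.DataFrame:
    """Per-sample IqR values and categories as a tidy frame."""
    rows = [
        {
            "sample_id": r.sample_id,
            "province": s.province,
            "iqr": r.iqr,
            "category": r.category,
        }
        for s in dataset.samples
        for r in [iqr_value(s, refs)]
    ]
    return pd.DataFrame(rows, columns=["sample_id", "province", "iqr", "category"])
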