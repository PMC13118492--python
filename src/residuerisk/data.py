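"""Data model and I/O for residue monitoring datasets.

A monitoring survey is stored sparsely: each quantified residue is one row of
a long-format CSV (``sample_id, province, analyte, concentration_mg_kg``) and
any (sample, analyte) pair of the panel without a row is a non-detect.  A row
with an empty analyte field marks a residue-free sample so that contaminated
and clean samples share one file.

Left-censored observations (below the limit of quantification, LOQ) are never
stored; they are substituted on demand by a :class:`CensoringPolicy`:
lower bound (LB) replaces non-detects with 0, middle bound (MB) with LOQ/2,
and upper bound (UB) with the LOQ itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnalyteLookupError, SchemaError, ValidationError

MONITORING_COLUMNS = ["sample_id", "province", "analyte", "concentration_mg_kg"]
REFERENCE_COLUMNS = [
    "analyte",
    "class",
    "authorised",
    "mrl_mg_kg",
    "adi_mg_kg_bw_day",
    "arfd_mg_kg_bw",
    "loq_mg_kg",
]

PESTICIDE_CLASSES = ("fungicide", "insecticide", "acaricide")


class CensoringPolicy(str, Enum):
    """Substitution rule for non-detects (left-censored observations)."""

    LB = "LB"
    MB = "MB"
    UB = "UB"

    def substitution(self, loq: float) -> float:
        """Value standing in for a non-detect under this policy."""
        if self is CensoringPolicy.LB:
            return 0.0
        if self is CensoringPolicy.MB:
            return 0.5 * loq
        return loq


@dataclass(frozen=True)
class PesticideRef:
    """Regulatory and toxicological constants for one analyte.

    Parameters
    ----------
    name : analyte identifier (unique within a reference table)
    pclass : pesticide class, one of ``fungicide``/``insecticide``/``acaricide``
    authorised : whether the substance is authorised for the commodity
    mrl : maximum residue level, mg/kg
    adi : acceptable daily intake, mg/kg bw/day
    arfd : acute reference dose, mg/kg bw (``None`` when not established)
    loq : limit of quantification of the method, mg/kg
    """

    name: str
    pclass: str
    authorised: bool
    mrl: float
    adi: float | None
    loq: float
    arfd: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("analyte name must be non-empty")
        if self.pclass not in PESTICIDE_CLASSES:
            raise ValidationError(
                f"{self.name}: class {self.pclass!r} not in {PESTICIDE_CLASSES}"
            )
        for label, value in (("mrl", self.mrl), ("loq", self.loq)):
            if not (value > 0) or not math.isfinite(value):
                raise ValidationError(f"{self.name}: {label} must be positive, got {value}")
        # ADI/ARfD may be unestablished (None); risk stages then exclude or
        # fall back as appropriate.
        for label, value in (("adi", self.adi), ("arfd", self.arfd)):
            if value is not None and not (value > 0):
                raise ValidationError(f"{self.name}: {label} must be positive when present")


class ReferenceTable:
    """Keyed collection of :class:`PesticideRef` entries."""

    def __init__(self, refs: Iterable[PesticideRef]):
        self._refs: dict[str, PesticideRef] = {}
        for ref in refs:
            if ref.name in self._refs:
                raise ValidationError(f"duplicate analyte in reference table: {ref.name}")
            self._refs[ref.name] = ref

    def __getitem__(self, name: str) -> PesticideRef:
        try:
            return self._refs[name]
        except KeyError:
            raise AnalyteLookupError(f"analyte not in reference table: {name}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._refs

    def __iter__(self):
        return iter(self._refs.values())

    def __len__(self) -> int:
        return len(self._refs)

    @property
    def analytes(self) -> list[str]:
        return list(self._refs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path)
        missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"reference table missing columns: {missing}")
        refs = []
        for row in df.to_dict("records"):
            arfd = row["arfd_mg_kg_bw"]
            adi = row["adi_mg_kg_bw_day"]
            refs.append(
                PesticideRef(
                    name=str(row["analyte"]),
                    pclass=str(row["class"]),
                    authorised=_parse_bool(row["authorised"]),
                    mrl=float(row["mrl_mg_kg"]),
                    adi=None if pd.isna(adi) else float(adi),
                    arfd=None if pd.isna(arfd) else float(arfd),
                    loq=float(row["loq_mg_kg"]),
                )
            )
        return cls(refs)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "analyte": r.name,
                "class": r.pclass,
                "authorised": r.authorised,
                "mrl_mg_kg": r.mrl,
                "adi_mg_kg_bw_day": "" if r.adi is None else r.adi,
                "arfd_mg_kg_bw": "" if r.arfd is None else r.arfd,
                "loq_mg_kg": r.loq,
            }
            for r in self
        ]
        pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean: {value!r}")


@dataclass
class SampleRecord:
    """One monitored sample: its region label and quantified residues only."""

    sample_id: str
    province: str
    detections: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for analyte, conc in self.detections.items():
            if not (conc > 0) or not math.isfinite(conc):
                raise ValidationError(
                    f"sample {self.sample_id}: non-positive concentration for {analyte}"
                )

    @property
    def n_residues(self) -> int:
        return len(self.detections)


@dataclass
class MonitoringDataset:
    """A residue monitoring survey: samples, analyte panel, region roster."""

    samples: list[SampleRecord]
    panel: list[str]
    provinces: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        panel = set(self.panel)
        for s in self.samples:
            unknown = set(s.detections) - panel
            if unknown:
                raise ValidationError(
                    f"sample {s.sample_id}: analytes not in panel: {sorted(unknown)}"
                )
        if not self.provinces:
            roster: dict[str, int] = {}
            for s in self.samples:
                roster[s.province] = roster.get(s.province, 0) + 1
            self.provinces = roster
        else:
            counts: dict[str, int] = {p: 0 for p in self.provinces}
            for s in self.samples:
                if s.province not in counts:
                    raise ValidationError(
                        f"sample {s.sample_id}: province {s.province!r} not in roster"
                    )
                counts[s.province] += 1
            if counts != dict(self.provinces):
                raise ValidationError(
                    f"province roster {self.provinces} does not match sample counts {counts}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def detections_frame(self) -> pd.DataFrame:
        """Long-format view of all quantified residues (one row per detection)."""
        rows = [
            {
                "sample_id": s.sample_id,
                "province": s.province,
                "analyte": analyte,
                "concentration_mg_kg": conc,
            }
            for s in self.samples
            for analyte, conc in sorted(s.detections.items())
        ]
        return pd.DataFrame(rows, columns=MONITORING_COLUMNS)


def read_monitoring_table(
    path: str | Path,
    refs: ReferenceTable | None = None,
    panel: list[str] | None = None,
) -> MonitoringDataset:
    """Read a long-format monitoring CSV into a :class:`MonitoringDataset`.

    A row with an empty ``analyte`` field declares a residue-free sample.
    When ``refs`` is given, analytes must exist in the reference table and
    concentrations below the analyte LOQ are rejected (only quantified
    residues are reportable).  ``panel`` defaults to the reference table's
    analytes, or to the analytes observed in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "province": str, "analyte": str})
    missing = [c for c in MONITORING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"monitoring table missing columns: {missing}")

    seen_pairs: set[tuple[str, str]] = set()
    order: list[str] = []
    records: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        province = str(row.province)
        analyte = row.analyte
        blank = pd.isna(analyte) or str(analyte).strip() == ""
        if sid not in records:
            records[sid] = SampleRecord(sample_id=sid, province=province)
            order.append(sid)
        elif records[sid].province != province:
            raise ValidationError(f"sample {sid}: conflicting province labels")
        if blank:
            continue
        analyte = str(analyte)
        conc = row.concentration_mg_kg
        if pd.isna(conc):
            raise ValidationError(f"sample {sid}: missing concentration for {analyte}")
        conc = float(conc)
        if conc < 0:
            raise ValidationError(f"sample {sid}: negative concentration for {analyte}")
        if (sid, analyte) in seen_pairs:
            raise ValidationError(f"duplicate detection row: ({sid}, {analyte})")
        seen_pairs.add((sid, analyte))
        if refs is not None:
            if analyte not in refs:
                raise AnalyteLookupError(f"unknown analyte in monitoring table: {analyte}")
            if conc < refs[analyte].loq:
                raise ValidationError(
                    f"sample {sid}: {analyte} concentration {conc} below LOQ "
                    f"{refs[analyte].loq}; only quantified residues are accepted"
                )
        records[sid].detections[analyte] = conc

    if panel is None:
        panel = refs.analytes if refs is not None else sorted(
            {a for r in records.values() for a in r.detections}
        )
    return MonitoringDataset(samples=[records[sid] for sid in order], panel=list(panel))


def write_monitoring_table(dataset: MonitoringDataset, path: str | Path) -> None:
    """Write the dataset back to canonical long-format CSV.

    Samples keep dataset order; residues within a sample are sorted by
    analyte; residue-free samples are written as a single row with empty
    analyte and concentration fields.  Re-writing a read dataset is
    byte-identical, which makes round trips checkable.
    """
    lines = [",".join(MONITORING_COLUMNS)]
    for s in dataset.samples:
        if not s.detections:
            lines.append(f"{s.sample_id},{s.province},,")
            continue
        for analyte in sorted(s.detections):
            conc = repr(s.detections[analyte])
            lines.append(f"{s.sample_id},{s.province},{analyte},{conc}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def substitute_censored(
    dataset: MonitoringDataset,
    analyte: str,
    policy: CensoringPolicy,
    refs: ReferenceTable,
) -> np.ndarray:
    """Concentration vector for one analyte with non-detects substituted.

    Detected values pass through unchanged; non-detects take the policy's
    substitution value (0, LOQ/2 or LOQ).  The vector follows dataset sample
    order, so elementwise LB <= MB <= UB holds by construction.
    """
    if analyte not in dataset.panel:
        raise AnalyteLookupError(f"analyte not in monitoring panel: {analyte}")
    sub = CensoringPolicy(policy).substitution(refs[analyte].loq)
    return np.array(
        [s.detections.get(analyte, sub) for s in dataset.samples], dtype=float
    )


def mean_concentration(
    dataset: MonitoringDataset,
    analyte: str,
    policy: CensoringPolicy,
    refs: ReferenceTable,
) -> float:
    """Arithmetic mean of the substituted concentration vector (mg/kg)."""
    if dataset.n_samples == 0:
        raise ValidationError("cannot compute a mean concentration on an empty dataset")
    return float(np.mean(substitute_censored(dataset, analyte, policy, refs)))
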