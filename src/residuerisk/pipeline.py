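"""End-to-end orchestration of the monitoring analysis.

A :class:`PipelineConfig` names the inputs (monitoring CSV, reference CSV,
optional validation replicates and exposure overrides) and the stages to
run; :func:`run_pipeline` executes occurrence statistics, IqR quality
profiling, deterministic exposure and, optionally, the Monte Carlo stage,
writing CSV tables and JSON summaries plus a manifest that pins the seed and
a hash of the configuration so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import CensoringPolicy, MonitoringDataset, ReferenceTable, read_monitoring_table
from .errors import ResidueRiskError, ValidationError
from .exposure import ExposureParams, scenario_report
from .iqr import iqr_table, quality_profile
from .mcs import MCSConfig, build_spec, run_mcs, sensitivity_analysis
from .occurrence import chi2_homogeneity, exceedance_table, multi_residue_distribution, prevalence_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    monitoring_csv: str
    reference_csv: str
    out_dir: str
    policies: tuple[str, ...] = ("LB", "MB", "UB")
    seed: int = 0
    mcs_iterations: int = 10_000
    run_mcs_stage: bool = True
    mcs_policy: str = "UB"
    consumption_cv: float = 0.30
    bw_cv: float = 0.15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "policies" in raw:
            raw["policies"] = tuple(raw["policies"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class ReportBundle:
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all configured stages and write the report bundle.

    The deterministic stages run first; the Monte Carlo stage is optional
    and its failure (or absence) never perturbs deterministic outputs.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not Path(config.monitoring_csv).exists():
        raise FileNotFoundError(config.monitoring_csv)
    if not Path(config.reference_csv).exists():
        raise FileNotFoundError(config.reference_csv)

    refs = ReferenceTable.from_csv(config.reference_csv)
    dataset = read_monitoring_table(config.monitoring_csv, refs=refs)
    logger.info("loaded %d samples, %d analytes on panel",
                dataset.n_samples, len(dataset.panel))
    bundle = ReportBundle(out_dir=out_dir)
    policies = tuple(CensoringPolicy(p) for p in config.policies)
    if not policies:
        raise ValidationError("at least one censoring policy must be configured")

    # occurrence statistics
    prevalence = prevalence_summary(dataset, refs)
    _write_csv(prevalence, out_dir / "prevalence.csv", index=True)
    bundle.artifacts["prevalence"] = out_dir / "prevalence.csv"

    hist = multi_residue_distribution(dataset)
    hist.to_frame().to_csv(out_dir / "multi_residue.csv")
    bundle.artifacts["multi_residue"] = out_dir / "multi_residue.csv"

    exceedance = exceedance_table(dataset, refs)
    _write_csv(exceedance.detections, out_dir / "exceedance.csv")
    bundle.artifacts["exceedance"] = out_dir / "exceedance.csv"

    provinces = [p for p in prevalence.index if p != "overall"]
    chi2_out = {}
    if len(provinces) >= 2:
        det = chi2_homogeneity(
            prevalence.loc[provinces, "n_contaminated"],
            prevalence.loc[provinces, "n_samples"],
        )
        chi2_out["detection"] = dataclasses.asdict(det)
        contaminated = prevalence.loc[provinces, "n_contaminated"]
        if (contaminated > 0).all():
            exc = chi2_homogeneity(
                prevalence.loc[provinces, "n_exceeding_mrl"], contaminated
            )
            chi2_out["exceedance"] = dataclasses.asdict(exc)
    (out_dir / "chi2.json").write_text(json.dumps(chi2_out, indent=2))
    bundle.artifacts["chi2"] = out_dir / "chi2.json"

    # IqR quality stage
    _write_csv(iqr_table(dataset, refs), out_dir / "iqr_samples.csv")
    _write_csv(quality_profile(dataset, refs), out_dir / "iqr_profile.csv", index=True)
    bundle.artifacts["iqr_samples"] = out_dir / "iqr_samples.csv"
    bundle.artifacts["iqr_profile"] = out_dir / "iqr_profile.csv"

    # deterministic exposure
    report = scenario_report(dataset, refs, policies=policies)
    _write_csv(report.chronic, out_dir / "chronic_exposure.csv")
    _write_csv(report.acute, out_dir / "acute_exposure.csv")
    _write_csv(report.contributions, out_dir / "hic_contributions.csv")
    hi_payload = {
        "hazard_indices": report.hazard_indices.to_dict(orient="records"),
        "excluded_no_adi": report.excluded,
    }
    (out_dir / "hazard_indices.json").write_text(json.dumps(hi_payload, indent=2))
    for key in ("chronic_exposure", "acute_exposure", "hic_contributions",
                "hazard_indices"):
        suffix = ".json" if key == "hazard_indices" else ".csv"
        bundle.artifacts[key] = out_dir / f"{key}{suffix}"

    # probabilistic stage (optional, isolated)
    mcs_summary = None
    if config.run_mcs_stage:
        try:
            for params in (ExposureParams.adult(), ExposureParams.child()):
                spec = build_spec(
                    dataset, refs, CensoringPolicy(config.mcs_policy), params,
                    consumption_cv=config.consumption_cv, bw_cv=config.bw_cv,
                )
                result = run_mcs(spec, refs, MCSConfig(
                    iterations=config.mcs_iterations, seed=config.seed,
                    population=params.population,
                ))
                sens = sensitivity_analysis(result.inputs, result.hi_samples)
                _write_csv(sens.contributions,
                           out_dir / f"sensitivity_{params.population}.csv")
                summary = {
                    "population": params.population,
                    "iterations": result.config.iterations,
                    "seed": result.config.seed,
                    "hi_mean": result.mean,
                    "hi_median": result.median,
                    "hi_p5": result.p5,
                    "hi_p95": result.p95,
                    "prob_exceed_unity": result.prob_exceed_unity,
                    "adi_exceedance": result.adi_exceedance,
                }
                path = out_dir / f"mcs_{params.population}.json"
                path.write_text(json.dumps(summary, indent=2))
                bundle.artifacts[f"mcs_{params.population}"] = path
                bundle.artifacts[f"sensitivity_{params.population}"] = (
                    out_dir / f"sensitivity_{params.population}.csv"
                )
                mcs_summary = summary
        except ResidueRiskError as err:
            logger.warning("Monte Carlo stage skipped: %s", err)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "n_samples": dataset.n_samples,
        "n_panel": len(dataset.panel),
        "elapsed_s": round(time.time() - t0, 3),
        "artifacts": {k: str(v.name) for k, v in bundle.artifacts.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle.manifest = manifest
    bundle.artifacts["manifest"] = out_dir / "manifest.json"
    return bundle
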