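# residuerisk

Statistics and dietary risk assessment for pesticide residue monitoring
surveys of a single commodity (the bundled defaults emulate a gherkin
survey across five production provinces, but nothing is crop-specific).

It is aimed at food-control laboratories and risk assessors who hold a
long-format table of quantified residues (sample, region, analyte,
concentration in mg/kg) plus a reference table of regulatory constants
(MRL, ADI, ARfD, LOQ), and want the full analysis chain:

* **Occurrence statistics** — prevalence per region, multi-residue
  histograms, MRL exceedances, and Pearson χ² homogeneity tests of
  detection/exceedance rates across regions.
* **Index of Quality for Residues (IqR)** — per sample,
  `IqR = Σᵢ PRCᵢ / MRLᵢ` over the quantified residues, classified as
  excellent (IqR = 0), good (0 < IqR ≤ 0.6), acceptable (0.6 < IqR ≤ 1)
  or unacceptable (IqR > 1).
* **Matrix risk ranking** — composite score
  `S = (A + B) × (C + D + E) × F` from acute toxicity, potency, dietary
  contribution, application frequency (FOD = 100·N/P), vulnerable-group and
  residue-level (`F = (F₀·1 + F₁·2 + F₂·3 + F₃·4)/n`) components;
  high ≥ 20, medium 15–20, low < 15.
* **Deterministic exposure** — chronic `NEDI = c̄ × consumption / bw`,
  `HQc = NEDI/ADI`; acute IESTI Case 2a
  `IESTI = (Ue·HR·v + (LP − Ue)·HR)/bw`, `HQa = IESTI/ARfD` (ADI fallback);
  hazard indices `HI = Σ HQ` with acceptability at HI < 1. Non-detects are
  substituted under lower/middle/upper-bound censoring policies
  (0, LOQ/2, LOQ), so every chronic figure comes as an LB ≤ MB ≤ UB triple.
* **Probabilistic risk** — Monte Carlo simulation of the chronic hazard
  index (log-normal residues and consumption, truncated-normal body
  weight), percentile summaries, ADI-exceedance probabilities, and
  contribution-to-variance sensitivity analysis.
* **Method-validation metrics** — recovery, RSDr/RSD_WR, LOQ, expanded
  uncertainty (k·√(bias² + RSD_WR²)), calibration linearity and
  identification tolerances, with SANTE-style inclusive acceptability
  windows (recovery 70–120%, RSD ≤ 20%).
* **Synthetic survey generator** — truncated log-normal concentration laws
  built from printed summary statistics, with a latent-propensity
  co-occurrence model that reproduces heavy multi-residue tails at exact
  marginal detection frequencies.

## Worked example

```python
import residuerisk as rr
from residuerisk.synthetic import (
    PROVINCE_SIZES, default_survey_specs, synthetic_reference_table,
)

ds = rr.generate_dataset(default_survey_specs(), PROVINCE_SIZES,
                         rr.CooccurrenceModel(1.0), seed=1)
refs = synthetic_reference_table()   # synthetic stand-in constants

prev = rr.prevalence_summary(ds, refs)
print(prev.loc["overall", ["n_samples", "n_contaminated"]])
# n_samples         905
# n_contaminated    566

provs = [p for p in prev.index if p != "overall"]
chi2 = rr.chi2_homogeneity(prev.loc[provs, "n_contaminated"],
                           prev.loc[provs, "n_samples"])
print(round(chi2.statistic, 2), chi2.df)   # 2.34 4

report = rr.scenario_report(ds, refs)
print(report.hazard_indices.head(3))
#   population policy     kind        hi  acceptable
# 0      adult     LB  chronic  0.000023        True
# 1      adult     MB  chronic  0.000069        True
# 2      adult     UB  chronic  0.000116        True
```

In this run 566 of 905 synthetic samples carried at least one quantified
residue; the χ² test finds no significant regional heterogeneity for this
seed (the generator applies no regional odds multipliers by default); and
the adult chronic hazard index stays around 10⁻⁴ even under the
upper-bound censoring scenario — orders of magnitude below the HI = 1
threshold of concern, matching the qualitative conclusion such surveys
usually reach. A single-residue sample with metalaxyl at 0.343 mg/kg
against an MRL of 0.01 mg/kg scores `IqR = 34.3` ("unacceptable"):

```python
refs = rr.ReferenceTable([rr.PesticideRef(
    "metalaxyl", "fungicide", True, mrl=0.01, adi=0.08, loq=0.01)])
r = rr.iqr_value(rr.SampleRecord("S1", "Manisa", {"metalaxyl": 0.343}), refs)
print(r.iqr, r.category)   # 34.3 unacceptable
```

## Command line

```bash
residuerisk synth --spec-csv specs.csv -n Manisa=214 -n Izmir=152 \
    --seed 1 --out monitoring.csv
residuerisk summarize --monitoring monitoring.csv --reference refs.csv \
    --out-dir out/
residuerisk run --config pipeline.yaml --seed 1
```

`run` executes every stage and writes CSV tables, JSON summaries and a
manifest (package version, seed, config hash) that makes a run
reproducible bit-for-bit.

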