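# Methods

## Data model and left-censoring

A monitoring survey is stored sparsely: each quantified residue is one row
(`sample_id, province, analyte, concentration_mg_kg`); any panel analyte
without a row for a sample is a non-detect, and a row with a blank analyte
marks a residue-free sample. Concentrations below the analyte's limit of
quantification (LOQ) are rejected at read time: the model assumes the
laboratory reports quantified residues only, with nothing between LOD and
LOQ.

Non-detects are left-censored observations. They are never imputed in
storage; instead every consumer substitutes them on demand under one of
three policies — lower bound (LB, 0), middle bound (MB, LOQ/2), upper bound
(UB, LOQ). Because the substitution value is monotone in the policy, every
derived chronic quantity (mean concentration, NEDI, HQc, HIc) satisfies
LB ≤ MB ≤ UB elementwise, which the test suite asserts as a property.
Detection counts and MRL exceedances are invariant under the policy
(a non-detect can never exceed).

## Occurrence statistics

Prevalence tables count contaminated samples, distinct residues, distinct
unauthorised analytes and MRL-exceeding samples per region and overall.
Exceedance uses a strict inequality — a residue exactly at the MRL is
compliant by definition. Regional homogeneity of rates is tested with the
Pearson χ² statistic on the 2 × k success/failure table without continuity
correction (k > 2 groups), df = k − 1; the implementation is checked against
a brute-force Σ(O−E)²/E oracle to 10⁻⁹ on a thousand random tables. When
testing exceedance homogeneity, the natural denominators are the
contaminated samples per region, not all samples: only a contaminated
sample can exceed.

## Index of Quality for Residues

Per sample, IqR = Σᵢ PRCᵢ/MRLᵢ over quantified residues (non-detects
contribute zero). Categories: excellent (IqR = 0), good (0 < IqR ≤ 0.6),
acceptable (0.6 < IqR ≤ 1.0), unacceptable (> 1.0); boundaries fall to the
lower category, and "adequate" is accepted as an alias for "acceptable"
since the literature uses both names for the (0.6, 1] band. The index is
additive over residues and strictly monotone in every concentration.

## Matrix risk ranking

The composite score combines acute toxicity (A, from LD50), toxic potency
(B, from ADI), dietary contribution (C), application frequency (D, from
FOD = 100·N/P with N applications over a P-day growth period), a
vulnerable-group component (E, defaulting to 3 when no evidence singles out
a high-exposure subgroup), and the residue-level score
F = (F₀·1 + F₁·2 + F₂·3 + F₃·4)/n ∈ [1, 4], where the bands are
no-residue, below-MRL, 1–10× MRL (inclusive at both edges) and > 10× MRL.

The printed form of the composite formula in the source matrix literature is
typographically ambiguous; this package evaluates
S = (A + B) × (C + D + E) × F — the grouping of the original veterinary
residues prioritisation matrix — and exposes the grouping as a callable for
users who need a variant. Categories use half-open intervals: high [20, ∞),
medium [15, 20), low [0, 15), resolving the overlap in common prose
statements of the thresholds. The default scoring bands for A–D in
`ranking.DEFAULT_BANDS` are order-of-magnitude reconstructions of the
matrix's intent and are deliberately user-editable; they are not a
transcription of any authority's table. Pesticides without an established
ADI cannot receive a B component and are excluded from scoring, mirroring
standard practice.

## Deterministic exposure

Chronic: NEDI = mean concentration × consumption / body weight, in
mg/kg bw/day; HQc = NEDI/ADI. Defaults: consumption 0.0011 kg/day (adult)
and 0.0004 kg/day (child); body weights 70 and 23 kg.

Acute: IESTI Case 2a, applicable when the edible-unit weight satisfies
25 g ≤ Ue < LP:

    IESTI = (Ue · HR · v + (LP − Ue) · HR) / bw

with Ue = 0.0544 kg, variability factor v = 3, large portions LP = 0.168 kg
(adult) and 0.092 kg (child), and HR the highest observed concentration of
the pesticide. Only Case 2a is implemented; parameters outside its
applicability raise instead of silently switching case, because silent case
changes are a classic source of irreproducible intake figures. HQa uses
the ARfD, falling back to the ADI (conservative, flagged in the output)
when none is established.

Hazard indices sum the quotients over detected pesticides only — not the
full analytical panel — and acceptability is strict (HI < 1; exactly 1 is
flagged as a concern).

## Probabilistic simulation

The Monte Carlo stage models residue concentrations and consumption as
log-normal and body weight as a normal truncated to positive values by
resampling (never clipping). Residue parameters are fitted by method of
moments on the substituted concentration vectors; under LB, substituted
zeros are floored at half the smallest positive LOQ in the panel
(configurable) before the log-transform, and an all-zero vector raises with
a hint to use MB or UB. Consumption and body weight enter as distributions
widened from their point defaults with coefficients of variation 30% and
15% respectively — typical spreads for dietary surveys when only means are
available; both are parameters.

Each of the (default) 10,000 iterations draws one concentration per
pesticide plus one consumption and one body-weight value shared across
pesticides, all independent — no correlation structure is assumed between
pesticides or between intake factors. Outputs: HIc mean/median/5th/95th
percentiles, P(HIc > 1), and per-pesticide P(HQ > 1). All draws come from
one seeded numpy PCG64 generator, making results a pure function of
(spec, config); the pipeline manifest records the seed.

Sensitivity analysis reports contribution-to-variance as the signed squared
Spearman rank correlation between each input and HIc, normalised so the
absolute contributions sum to 100% — the convention of the spreadsheet risk
tools practitioners use; a standardized-regression-coefficient variant is
available via `method="src"`. Zero-variance inputs contribute 0 with a
warning.

## Method-validation metrics

Recovery = 100·measured/spiked; RSDs use the sample (n−1) standard
deviation, since replicate sets are samples. RSD_WR pools the raw value set
across all day/analyst groups (total RSD) rather than decomposing variance
by ANOVA — documented and swappable, as the two differ when group means
shift. LOQ = 10 × sd of n = 10 fortified-blank replicates. Expanded
uncertainty follows the top-down route U = k·√(bias² + RSD_WR²) with k = 2;
bias enters as mean absolute deviation of recovery from 100% across levels
(the alternative RMS-bias convention would be a one-line change).
Identification requires |Δrt| ≤ 0.1 min and ion-ratio deviation ≤ 30%;
all acceptability windows (recovery 70–120%, RSD ≤ 20%, boundaries
included) are guarded against binary representation error so a deviation of
exactly the tolerance passes.

## Synthetic survey generator

The generator exists so the full pipeline is testable without access to raw
survey data. Each analyte's occurrence is (p_detect, truncated log-normal
concentration law); `build_spec_from_summary` converts printed summary
statistics (frequency, min, mean, max) into a spec by fixing the log-scale
spread at σ = log(cmax/cmin)/4 (the range spans about four standard
deviations) and solving the location numerically so the truncated mean
matches the printed mean within 5%. Sampling is inverse-CDF, so a dataset
is a pure function of the seed.

Multi-residue co-occurrence is produced by a per-sample latent gamma
propensity (mean 1, variance = `dispersion`) multiplying every analyte's
detection odds; base odds are calibrated by numerical integration over the
gamma law so the *marginal* detection frequency equals p_detect exactly.
Dispersion 0 gives independent detections; increasing it fattens the
per-sample residue-count tail (up to 7–8 residues per sample at dispersion
1, the bundled default) without moving the margins. This latent-propensity
structure is an assumption — real application patterns correlate specific
analyte pairs (e.g. co-formulated products), which the single shared factor
cannot represent.

The bundled default panel covers the fifteen most frequently observed
analytes of the emulated survey with their printed detection frequencies
and concentration ranges at province sizes 280/104/152/214/155 (n = 905).
Analytes whose mean concentration was not printed (frequencies ≤ 10%) use
the geometric midpoint of their range, the natural central value for
right-skewed data. `synthetic_reference_table()` supplies *synthetic*
stand-in MRL/ADI/ARfD constants for demonstrations and tests; real
assessments must load a reference CSV from the applicable regulatory
database.

Passing tests on generated data therefore demonstrate the correctness of
the statistical machinery under the stated occurrence model, not the
reproduction of any particular survey's dataset-dependent headline numbers,
which require the original raw data.

## Numerical choices and problem sizes

Truncated log-normal means are computed from normal CDFs in closed form and
cross-checked in tests against quadrature of x·pdf(x). Root finding uses
Brent's method on brackets guaranteed to contain a sign change (the
truncated mean is continuous and monotone in μ between the truncation
bounds). The test suite runs the Monte Carlo checks at 10,000 iterations
and the censoring-monotonicity sweep over 100 generated surveys of 30
samples × 3 analytes — sizes chosen so that the whole suite completes in a
few seconds while keeping Monte Carlo standard errors small relative to
the asserted tolerances.

## Known limitations

* Chronic exposure uses a single mean-consumption figure per population;
  no consumption-survey percentiles or consumer-only adjustment.
* No processing factors (washing, peeling, pickling) and no
  cumulative-assessment-group weighting of toxicologically similar
  compounds; hazard quotients are summed unweighted.
* The acute assessment covers IESTI Case 2a only.
* Probabilistic modelling is 1-D (variability only); no nested
  variability/uncertainty simulation and no Bayesian treatment of
  distribution-parameter uncertainty.
* The co-occurrence model's single latent factor cannot encode pairwise
  analyte correlations.
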