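import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from residuerisk import (
    CensoringPolicy,
    DistributionSpec,
    ExposureParams,
    LogNormalParams,
    MCSConfig,
    MonitoringDataset,
    PesticideRef,
    ReferenceTable,
    SampleRecord,
    fit_distributions,
    run_mcs,
    sensitivity_analysis,
)
from residuerisk.errors import ValidationError
from residuerisk.mcs import NormalParams, build_spec


def make_dataset(values, analyte="x", loq=0.01):
    refs = ReferenceTable(
        [PesticideRef(analyte, "fungicide", True, mrl=1.0, adi=0.01, loq=loq)]
    )
    samples = [
        SampleRecord(f"S{i}", "P", {analyte: float(v)} if v > 0 else {})
        for i, v in enumerate(values)
    ]
    return MonitoringDataset(samples=samples, panel=[analyte]), refs


class TestFit:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(12)
        mu, sigma = -3.0, 0.5
        values = np.exp(rng.normal(mu, sigma, size=2000))
        ds, refs = make_dataset(values)
        fitted = fit_distributions(ds, refs, CensoringPolicy.UB)["x"]
        assert fitted.mu == pytest.approx(mu, rel=0.05)
        assert fitted.sigma == pytest.approx(sigma, rel=0.05)

    def test_constant_values_degenerate(self):
        ds, refs = make_dataset([0.05] * 10)
        fitted = fit_distributions(ds, refs, CensoringPolicy.UB)["x"]
        assert fitted.sigma == 0.0
        assert math.exp(fitted.mu) == pytest.approx(0.05)

    def test_single_value_rejected(self):
        ds, refs = make_dataset([0.05])
        with pytest.raises(ValidationError):
            fit_distributions(ds, refs, CensoringPolicy.UB)

    def test_all_zero_lb_vector_suggests_other_policy(self):
        # an analyte with no detections has an all-zero LB vector
        ds, refs = make_dataset([0.0, 0.0, 0.0])
        with pytest.raises(ValidationError, match="MB or UB"):
            fit_distributions(ds, refs, CensoringPolicy.LB, analytes=["x"])
        # the same request succeeds under UB (degenerate at the LOQ)
        fitted = fit_distributions(ds, refs, CensoringPolicy.UB, analytes=["x"])
        assert math.exp(fitted["x"].mu) == pytest.approx(0.01)


class TestRun:
    def test_degenerate_collapse_to_deterministic(self):
        refs = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, 0.01, 0.01)]
        )
        spec = DistributionSpec(
            residues={"x": LogNormalParams(mu=math.log(0.05), sigma=0.0)},
            consumption=LogNormalParams(mu=math.log(0.0011), sigma=0.0),
            bw=NormalParams(mean=70.0, sd=0.0),
        )
        result = run_mcs(spec, refs, MCSConfig(iterations=2000, seed=0))
        deterministic = 0.05 * 0.0011 / 70.0 / 0.01
        assert abs(result.mean - deterministic) < 1e-9
        assert result.p5 == result.p95 == pytest.approx(deterministic)

    def test_same_seed_identical(self):
        refs = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, 0.01, 0.01)]
        )
        spec = DistributionSpec(
            residues={"x": LogNormalParams(-3.0, 0.4)},
            consumption=LogNormalParams.from_mean_cv(0.0011, 0.3),
            bw=NormalParams(70.0, 10.0),
        )
        r1 = run_mcs(spec, refs, MCSConfig(iterations=500, seed=21))
        r2 = run_mcs(spec, refs, MCSConfig(iterations=500, seed=21))
        assert np.array_equal(r1.hi_samples, r2.hi_samples)
        assert r1.mean == r2.mean

    def test_tail_probability_matches_lognormal_cdf(self):
        # single pesticide, fixed consumption and bw: P(HQ > 1) has a closed
        # form in the concentration's log-normal law
        adi, cons, bw = 1e-6, 0.0011, 70.0
        mu, sigma = math.log(0.05), 0.6
        refs = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, adi, 0.01)]
        )
        spec = DistributionSpec(
            residues={"x": LogNormalParams(mu, sigma)},
            consumption=LogNormalParams(math.log(cons), 0.0),
            bw=NormalParams(bw, 0.0),
        )
        n = 10_000
        result = run_mcs(spec, refs, MCSConfig(iterations=n, seed=5))
        threshold = adi * bw / cons
        p_true = stats.norm.sf((math.log(threshold) - mu) / sigma)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(result.prob_exceed_unity - p_true) <= 3 * se

    def test_percentile_ordering(self):
        refs = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, 0.01, 0.01)]
        )
        spec = DistributionSpec(
            residues={"x": LogNormalParams(-3.0, 0.8)},
            consumption=LogNormalParams.from_mean_cv(0.0011, 0.3),
            bw=NormalParams(70.0, 10.0),
        )
        result = run_mcs(spec, refs, MCSConfig(iterations=2000, seed=3))
        assert result.p5 <= result.median <= result.p95

    def test_doubling_adi_halves_percentiles(self):
        spec = DistributionSpec(
            residues={"x": LogNormalParams(-3.0, 0.5)},
            consumption=LogNormalParams.from_mean_cv(0.0011, 0.3),
            bw=NormalParams(70.0, 10.0),
        )
        refs1 = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, 0.01, 0.01)]
        )
        refs2 = ReferenceTable(
            [PesticideRef("x", "fungicide", True, 1.0, 0.02, 0.01)]
        )
        r1 = run_mcs(spec, refs1, MCSConfig(iterations=1000, seed=6))
        r2 = run_mcs(spec, refs2, MCSConfig(iterations=1000, seed=6))
        for attr in ("mean", "median", "p5", "p95"):
            assert getattr(r2, attr) == pytest.approx(getattr(r1, attr) / 2, rel=1e-12)

    def test_build_spec_from_survey(self, survey_dataset, survey_refs):
        spec = build_spec(
            survey_dataset, survey_refs, CensoringPolicy.UB, ExposureParams.adult()
        )
        assert spec.residues
        assert spec.bw.mean == 70.0
        result = run_mcs(spec, survey_refs, MCSConfig(iterations=1000, seed=1))
        assert result.mean < 1.0  # chronic risk far below the concern threshold


class TestSensitivity:
    def test_single_varying_input_takes_all(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0, 0.5, 1000)
        inputs = pd.DataFrame({"conc:x": x, "consumption": np.full(1000, 0.0011)})
        with pytest.warns(UserWarning):
            sens = sensitivity_analysis(inputs, x * 2.0)
        by_input = sens.contributions.set_index("input")["contribution_pct"]
        assert by_input["conc:x"] == pytest.approx(100.0)
        assert by_input["consumption"] == 0.0

    def test_two_symmetric_inputs_split_evenly(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(0, 0.5, 10_000)
        b = rng.lognormal(0, 0.5, 10_000)
        inputs = pd.DataFrame({"a": a, "b": b})
        sens = sensitivity_analysis(inputs, a + b)
        by_input = sens.contributions.set_index("input")["contribution_pct"]
        assert by_input["a"] == pytest.approx(50.0, abs=5.0)
        assert by_input["b"] == pytest.approx(50.0, abs=5.0)

    def test_independent_input_contributes_little(self):
        rng = np.random.default_rng(10)
        a = rng.lognormal(0, 0.5, 10_000)
        noise = rng.lognormal(0, 0.5, 10_000)
        sens = sensitivity_analysis(pd.DataFrame({"a": a, "noise": noise}), a)
        by_input = sens.contributions.set_index("input")["contribution_pct"]
        assert abs(by_input["noise"]) < 1.0

    def test_absolute_contributions_sum_to_100(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(
            {f"v{i}": rng.lognormal(0, 0.3, 5000) for i in range(4)}
        )
        hi = frame.sum(axis=1).to_numpy()
        sens = sensitivity_analysis(frame, hi)
        assert sens.contributions["contribution_pct"].abs().sum() == pytest.approx(
            100.0, abs=0.1
        )

    def test_negative_relationship_is_signed(self):
        rng = np.random.default_rng(12)
        bw = rng.normal(70, 10, 5000)
        conc = rng.lognormal(-3, 0.5, 5000)
        hi = conc / bw
        sens = sensitivity_analysis(pd.DataFrame({"conc": conc, "bw": bw}), hi)
        by_input = sens.contributions.set_index("input")["contribution_pct"]
        assert by_input["bw"] < 0 < by_input["conc"]

    def test_src_method_available(self):
        rng = np.random.default_rng(13)
        a = rng.lognormal(0, 0.5, 2000)
        b = rng.lognormal(0, 0.5, 2000)
        sens = sensitivity_analysis(pd.DataFrame({"a": a, "b": b}), a + b,
                                    method="src")
        assert sens.contributions["contribution_pct"].abs().sum() == pytest.approx(100.0, abs=0.1)
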