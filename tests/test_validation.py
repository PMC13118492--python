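import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from residuerisk.errors import ValidationError
from residuerisk.validation import (
    FortifiedReplicateSet,
    ValidationReport,
    expanded_uncertainty,
    identification_check,
    linearity,
    loq_estimate,
    recovery_percent,
    rsd_percent,
    sante_compliance,
    validate_analyte,
    within_lab_rsd,
)


class TestRecovery:
    @pytest.mark.parametrize(
        "measured,spike,expected",
        [(0.008, 0.01, 80.0), (0.05, 0.05, 100.0), (0.00757, 0.01, 75.7)],
    )
    def test_direct_ratio(self, measured, spike, expected):
        assert recovery_percent(measured, spike) == pytest.approx(expected)

    def test_lowest_printed_recovery_is_compliant(self):
        report = ValidationReport("x", recovery_pct=75.7, rsdr_pct=5.0,
                                  rsdwr_pct=5.0, loq=0.01,
                                  expanded_uncertainty_pct=20.0, r_squared=0.999)
        assert sante_compliance(report)["recovery"]

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValidationError):
            recovery_percent(0.01, 0.0)


class TestRsd:
    def test_identical_values_zero(self):
        assert rsd_percent([2.0, 2.0, 2.0]) == 0.0

    def test_hand_value(self):
        # sd = 1, mean = 2
        assert rsd_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_single_value_error(self):
        with pytest.raises(ValidationError):
            rsd_percent([1.0])

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=12),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, values, c):
        x = np.array(values)
        assert rsd_percent(c * x) == pytest.approx(rsd_percent(x), abs=1e-7)


class TestWithinLab:
    def test_single_group_degenerates_to_rsd(self):
        g = FortifiedReplicateSet("x", 0.01, (1.0, 2.0, 3.0))
        assert within_lab_rsd([g]) == pytest.approx(rsd_percent(g.values))

    def test_identical_groups_of_constant_values(self):
        g1 = FortifiedReplicateSet("x", 0.01, (2.0, 2.0, 2.0), day="1")
        g2 = FortifiedReplicateSet("x", 0.01, (2.0, 2.0, 2.0), day="2")
        assert within_lab_rsd([g1, g2]) == 0.0

    def test_pooled_value_set(self):
        # pooled set {1,2,3,1,2,3}: sample sd 0.8944, mean 2 -> 44.72%
        g1 = FortifiedReplicateSet("x", 0.01, (1.0, 2.0, 3.0), day="1")
        g2 = FortifiedReplicateSet("x", 0.01, (1.0, 2.0, 3.0), day="2")
        expected = 100.0 * np.std([1, 2, 3, 1, 2, 3], ddof=1) / 2.0
        assert within_lab_rsd([g1, g2]) == pytest.approx(expected)
        assert within_lab_rsd([g1, g2]) == pytest.approx(44.7214, abs=1e-3)

    def test_empty_groups_error(self):
        with pytest.raises(ValidationError):
            within_lab_rsd([])


class TestLoq:
    def test_ten_times_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.01, 0.001, size=10)
        assert loq_estimate(x) == pytest.approx(10 * np.std(x, ddof=1))

    def test_all_equal_replicates_zero(self):
        assert loq_estimate([0.01] * 10) == pytest.approx(0.0, abs=1e-15)

    def test_replicate_count_enforced(self):
        with pytest.raises(ValidationError):
            loq_estimate([0.01, 0.02, 0.01], expected_n=10)
        with pytest.raises(ValidationError):
            loq_estimate([0.01])

    def test_symmetric_replicates_hand_sd(self):
        # 10 values symmetric around 0.010 with sample sd 0.0008 -> LOQ 0.008
        base = np.array([-1.5, -1.0, -0.5, -0.25, -0.1, 0.1, 0.25, 0.5, 1.0, 1.5])
        x = 0.010 + base / np.std(base, ddof=1) * 0.0008
        assert loq_estimate(x) == pytest.approx(0.008)


class TestUncertainty:
    def test_zero_inputs(self):
        assert expanded_uncertainty(0, 0, 2) == 0.0

    def test_hand_value(self):
        # 2 * sqrt(25 + 100) = 2 * sqrt(125)
        assert expanded_uncertainty(5, 10, 2) == pytest.approx(22.3607, abs=1e-3)

    def test_realistic_inputs_fall_in_survey_range(self):
        # bias/precision values typical of a compliant multi-residue method
        u = expanded_uncertainty(bias_pct=8.0, rsdwr_pct=12.0, k=2)
        assert 7.6 <= u <= 41.3

    @settings(max_examples=50, deadline=None)
    @given(
        b=st.floats(0, 50), r=st.floats(0, 50), c=st.floats(0.1, 10),
    )
    def test_monotone_and_homogeneous(self, b, r, c):
        base = expanded_uncertainty(b, r, 2)
        assert expanded_uncertainty(b + 1, r, 2) >= base
        assert expanded_uncertainty(b, r + 1, 2) >= base
        assert expanded_uncertainty(c * b, c * r, 2) == pytest.approx(c * base, rel=1e-9)


class TestLinearity:
    def test_perfectly_linear(self):
        levels = [0.005, 0.01, 0.05, 0.10, 0.25]
        responses = [10 * x + 1 for x in levels]
        assert linearity(levels, responses) == pytest.approx(1.0)

    def test_constant_responses(self):
        assert linearity([1, 2, 3], [5, 5, 5]) == 0.0

    def test_matches_correlation_squared_oracle(self):
        levels = np.array([0.005, 0.01, 0.05, 0.10, 0.25])
        rng = np.random.default_rng(3)
        responses = 200 * levels + rng.normal(0, 0.5, size=5)
        r = np.corrcoef(levels, responses)[0, 1]
        assert linearity(levels, responses) == pytest.approx(r * r, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            linearity([1, 2], [1, 2])


class TestIdentification:
    def test_pass_within_tolerances(self):
        res = identification_check(5.05, 5.00, 0.55, 0.50)
        assert res.rt_ok and res.ion_ratio_ok and res.ok

    def test_rt_failure(self):
        res = identification_check(5.15, 5.00, 0.50, 0.50)
        assert not res.rt_ok and not res.ok

    def test_inclusive_boundaries(self):
        assert identification_check(5.10, 5.00, 0.65, 0.50).rt_ok
        assert identification_check(5.00, 5.00, 0.65, 0.50).ion_ratio_ok  # 30% dev

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            identification_check(5.0, 5.0, 0.5, 0.0)


class TestCompliance:
    def test_survey_extremes_compliant(self):
        report = ValidationReport("x", recovery_pct=113.7, rsdr_pct=16.2,
                                  rsdwr_pct=19.76, loq=0.01,
                                  expanded_uncertainty_pct=41.3, r_squared=0.9995)
        flags = sante_compliance(report)
        assert flags["overall"]

    def test_low_recovery_non_compliant(self):
        report = ValidationReport("x", recovery_pct=65.0, rsdr_pct=5.0,
                                  rsdwr_pct=5.0, loq=0.01,
                                  expanded_uncertainty_pct=15.0, r_squared=0.9999)
        flags = sante_compliance(report)
        assert not flags["recovery"] and not flags["overall"]

    def test_rsd_boundary_inclusive(self):
        report = ValidationReport("x", recovery_pct=100.0, rsdr_pct=20.0,
                                  rsdwr_pct=20.0, loq=0.01,
                                  expanded_uncertainty_pct=15.0, r_squared=0.9999)
        assert sante_compliance(report)["rsdr"]

    def test_validate_analyte_end_to_end(self):
        rng = np.random.default_rng(8)
        groups = [
            FortifiedReplicateSet(
                "flonicamid", 0.01,
                tuple(rng.normal(0.0095, 0.0005, size=5)), day=str(d), analyst=a,
            )
            for d in range(1, 6)
            for a in ("A", "B")
        ]
        report = validate_analyte(
            groups,
            blank_replicates=rng.normal(0.01, 0.0008, size=10),
            levels=[0.005, 0.01, 0.05, 0.10, 0.25],
            responses=[1.1, 2.0, 10.1, 20.3, 50.2],
        )
        assert report.compliant["overall"]
        assert report.expanded_uncertainty_pct > 0
        assert math.isfinite(report.loq)
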