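"""Calibration with LOD/LOQ, precision, recovery, interference and
reference-method comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipvolt import (
    CalibrationCurve,
    compare_methods,
    fit_calibration,
    interference_change,
    interference_consistency,
    precision,
    recovery,
)
from mipvolt.data import table2_interference_path, table3_recovery_path
from mipvolt.validation import ValidationInputError

CALIBRATION_LEVELS_UM = (2.0, 10.0, 25.0, 40.0, 55.0, 70.0, 75.0)


class TestCalibration:
    def test_lod_loq_hand_example(self):
        conc = np.array(CALIBRATION_LEVELS_UM)
        model = fit_calibration(conc, 0.2 * conc + 0.05, blank_sd=0.01)
        assert model.lod == pytest.approx(0.165, rel=1e-9)  # 3.3 * 0.01 / 0.2
        assert model.loq == pytest.approx(0.5, rel=1e-9)  # 10 * 0.01 / 0.2
        assert model.sigma_source == "blank_replicates"
        assert model.linear_range == (model.lod, 75.0)

    def test_exact_line_has_unit_r_squared(self):
        conc = np.array(CALIBRATION_LEVELS_UM)
        model = fit_calibration(conc, 0.127 * conc + 0.01)
        assert model.r_squared == pytest.approx(1.0, rel=1e-12)
        assert model.slope == pytest.approx(0.127, rel=1e-9)

    @pytest.mark.parametrize("sigma", [1e-3, 0.01, 0.1])
    @pytest.mark.parametrize("slope", [0.05, 0.2, 1.0])
    def test_loq_lod_ratio_fixed_by_construction(self, sigma, slope):
        conc = np.array(CALIBRATION_LEVELS_UM)
        model = fit_calibration(conc, slope * conc + 0.02, blank_sd=sigma)
        assert model.loq / model.lod == pytest.approx(10.0 / 3.3, rel=1e-12)
        assert model.lod == pytest.approx(3.3 * sigma / slope, rel=1e-12)

    def test_lod_scaling_in_sigma_and_slope(self):
        conc = np.array(CALIBRATION_LEVELS_UM)
        base = fit_calibration(conc, 0.2 * conc + 0.02, blank_sd=0.01)
        double_sigma = fit_calibration(conc, 0.2 * conc + 0.02, blank_sd=0.02)
        double_slope = fit_calibration(conc, 0.4 * conc + 0.02, blank_sd=0.01)
        assert double_sigma.lod == pytest.approx(2 * base.lod, rel=1e-12)
        assert double_slope.lod == pytest.approx(base.lod / 2, rel=1e-12)

    def test_residual_sd_fallback_recorded(self):
        rng = np.random.default_rng(3)
        conc = np.array(CALIBRATION_LEVELS_UM)
        model = fit_calibration(conc, 0.2 * conc + 0.05 + rng.normal(0, 0.01, conc.size))
        assert model.sigma_source == "calibration_residuals"
        assert model.lod > 0

    def test_negative_slope_flagged_unusable(self):
        conc = np.array(CALIBRATION_LEVELS_UM)
        with pytest.warns(UserWarning, match="unusable"):
            model = fit_calibration(conc, 10.0 - 0.1 * conc)
        assert model.usable is False

    def test_quantify_inverts_predict(self):
        conc = np.array(CALIBRATION_LEVELS_UM)
        curve = CalibrationCurve().fit(conc, 0.2 * conc + 0.05)
        assert curve.quantify(curve.predict([30.0]))[0] == pytest.approx(30.0, rel=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValidationInputError):
            fit_calibration([1.0, 1.0, 2.0], [0.1, 0.1, 0.2])


@pytest.fixture(scope="module")
def table3():
    return pd.read_csv(table3_recovery_path())


class TestRecovery:

    def test_published_rows_reproduce(self, table3):
        # Two rows reproduce the printed percent exactly; the other two are
        # within the source's own rounding (<= 0.02%).
        for row in table3.itertuples(index=False):
            r = recovery([row.mean_uM], row.spiked_uM)
            assert r.recovery_pct == pytest.approx(row.printed_recovery_pct, abs=0.02)
        exact = recovery([38.98], 40.0)
        assert exact.recovery_pct == pytest.approx(97.45, abs=1e-9)
        assert recovery([23.71], 25.0).recovery_pct == pytest.approx(94.84, abs=1e-9)

    def test_perfect_recovery(self):
        r = recovery([40.0, 40.0, 40.0], 40.0)
        assert r.recovery_pct == 100.0
        assert r.rsd_pct == 0.0

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.floats(1e-3, 1e3, allow_nan=False))
    def test_unit_rescaling_invariance(self, scale):
        measured = np.array([22.0, 24.0, 26.0])
        base = recovery(measured, 25.0)
        scaled = recovery(measured * scale, 25.0 * scale)
        assert scaled.recovery_pct == pytest.approx(base.recovery_pct, rel=1e-9)
        assert scaled.rsd_pct == pytest.approx(base.rsd_pct, rel=1e-9)

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValidationInputError):
            recovery([1.0], 0.0)


class TestPrecision:
    def test_identical_replicates_have_zero_rsd(self):
        assert precision({10.0: [10, 10, 10]}).per_level_rsd[10.0] == 0.0

    def test_hand_computed_rsd(self):
        # sd = 1, mean = 10 -> 10%
        summary = precision({10.0: [9, 10, 11]})
        assert summary.per_level_rsd[10.0] == pytest.approx(10.0, rel=1e-12)

    def test_scale_invariance(self):
        a = precision({1.0: [9, 10, 11]}).per_level_rsd[1.0]
        b = precision({1.0: [45, 50, 55]}).per_level_rsd[1.0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_median_across_levels(self):
        summary = precision({1.0: [9, 10, 11], 2.0: [10, 10, 10], 3.0: [8, 10, 12]})
        assert summary.median_rsd == pytest.approx(10.0, rel=1e-9)

    def test_single_replicate_level_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            summary = precision({1.0: [10.0], 2.0: [9, 10, 11]})
        assert summary.skipped_levels == [1.0]
        assert list(summary.per_level_rsd) == [2.0]


class TestInterference:
    def test_backsolved_reference_row(self):
        r = interference_change(0.2311, 0.2311 - 0.039, "DSX", 100.0)
        assert r.delta_i == pytest.approx(-0.039, rel=1e-9)
        assert r.pct_change == pytest.approx(16.88, abs=0.01)

    def test_unperturbed_signal_changes_nothing(self):
        assert interference_change(0.2, 0.2, "X", 10.0).pct_change == 0.0

    def test_published_table_consistent_with_one_reference(self):
        table = pd.read_csv(table2_interference_path())
        check = interference_consistency(table)
        assert check.consistent  # all rows within 5% of a single reference
        assert check.reference_current == pytest.approx(0.2311, abs=5e-4)
        # exactly one row (propoxur at 50 uM) deviates beyond 2%
        assert len(check.flagged_rows) == 1
        flagged = table.iloc[check.flagged_rows[0]]
        assert (flagged["interferent"], flagged["conc_uM"]) == ("PPX", 50)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationInputError):
            interference_change(0.0, 0.1, "X", 1.0)


class TestMethodComparison:
    def test_identical_series_agree(self):
        x = [25.0, 40.0, 55.0, 70.0, 85.0]
        cmp = compare_methods(x, x)
        assert cmp.fit.slope == pytest.approx(1.0, rel=1e-12)
        assert cmp.fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert cmp.fit.r_squared == pytest.approx(1.0, rel=1e-12)
        assert cmp.agreement is True

    def test_configured_relation_recovered_exactly(self):
        x = np.array([25.0, 40.0, 55.0, 70.0, 85.0])
        cmp = compare_methods(x, 0.9972 * x + 1.6067)
        assert cmp.fit.slope == pytest.approx(0.9972, rel=1e-12)
        assert cmp.fit.intercept == pytest.approx(1.6067, rel=1e-9)
        assert cmp.agreement is True

    def test_doubled_reference_breaks_agreement(self):
        x = np.array([25.0, 40.0, 55.0])
        cmp = compare_methods(x, 2 * x)
        assert cmp.fit.slope == pytest.approx(2.0, rel=1e-12)
        assert cmp.agreement is False

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValidationInputError):
            compare_methods([1, 2, 3], [1, 2])
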