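"""Electron-transfer inference chain: regressions, Laviron and half-width
relations, electron count and control-regime classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipvolt import (
    Constants,
    Peak,
    bard_faulkner_alpha,
    classify_control,
    electron_count,
    fit_linear,
    generate_mechanism_study,
    laviron_alpha_n,
    mechanism_report,
    ph_dependence,
    scan_rate_analysis,
)
from mipvolt.mechanism import DegenerateDesignError, DomainError


def _peak(ep: float, ip: float = 1.0) -> Peak:
    return Peak(ep=ep, ip=ip, ep_half=ep - 0.09, baseline_slope=0.0, baseline_intercept=0.0)


class TestFitLinear:
    def test_exact_line(self):
        fit = fit_linear([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_convention(self):
        fit = fit_linear([1, 2, 3], [5, 5, 5])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_constant_x_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([2, 2, 2], [1, 2, 3])

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_slope_matches_two_pass_oracle(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) < 1e-3 or np.ptp(y) == 0:
            return
        # brute-force two-pass slope: cov(x, y) / var(x)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float(np.sum(xc * yc) / np.sum(xc * xc))
        assert fit_linear(x, y).slope == pytest.approx(oracle, rel=1e-7, abs=1e-9)


class TestPhDependence:
    def test_noiseless_slope_recovered_and_flagged(self):
        peaks = [(ph, _peak(0.736 + 0.0567 * (ph - 7))) for ph in range(3, 10)]
        fit, coupled = ph_dependence(peaks)
        assert fit.slope == pytest.approx(0.0567, rel=1e-12)
        assert coupled is True

    def test_flat_ep_is_not_proton_coupled(self):
        peaks = [(ph, _peak(0.736)) for ph in range(3, 10)]
        fit, coupled = ph_dependence(peaks)
        assert fit.slope == 0.0
        assert coupled is False

    def test_noisy_slope_within_its_confidence_interval(self):
        rng = np.random.default_rng(42)
        peaks = [
            (ph, _peak(0.736 + 0.0567 * (ph - 7) + rng.normal(0, 0.002)))
            for ph in range(3, 10)
        ]
        fit, _ = ph_dependence(peaks)
        lo, hi = fit.slope_ci(0.95)
        assert lo <= 0.0567 <= hi

    def test_needs_three_distinct_ph(self):
        with pytest.raises(ValueError, match="distinct pH"):
            ph_dependence([(7.0, _peak(0.7)), (7.0, _peak(0.7)), (8.0, _peak(0.8))])


class TestScanRateAnalysis:
    @pytest.mark.parametrize("exponent", [1.0, 0.5])
    def test_pure_power_laws_recovered_exactly(self, exponent):
        v = np.logspace(-1.3, 0, 6)
        peaks = [(u, _peak(0.7, ip=3.0 * u**exponent)) for u in v]
        loglog, _ = scan_rate_analysis(peaks)
        assert loglog.slope == pytest.approx(exponent, rel=1e-12)

    def test_nonpositive_current_rejected(self):
        peaks = [(u, _peak(0.7, ip=1.0)) for u in (0.1, 0.2, 0.4)]
        bad = Peak(0.7, 1.0, 0.61, 0.0, 0.0)
        object.__setattr__(bad, "ip", -1.0)  # bypass Peak's own guard
        with pytest.raises(DomainError):
            scan_rate_analysis(peaks[:2] + [(0.8, bad)])


class TestClassifyControl:
    @pytest.mark.parametrize(
        "slope, regime",
        [
            (0.7677, "mixed"),
            (0.50, "diffusion"),
            (1.00, "adsorption"),
            (0.55, "diffusion"),  # inclusive toward the pure regime
            (0.95, "adsorption"),
            (0.56, "mixed"),
        ],
    )
    def test_regimes(self, slope, regime):
        assert classify_control(slope) == regime

    def test_monotone_in_slope(self):
        order = {"diffusion": 0, "mixed": 1, "adsorption": 2}
        grid = np.linspace(0.0, 1.5, 151)
        codes = [order[classify_control(s)] for s in grid]
        assert codes == sorted(codes)

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            classify_control(float("nan"))


class TestLaviron:
    def test_printed_slope_evaluates_to_0582(self):
        assert laviron_alpha_n(0.1016) == pytest.approx(0.582, abs=5e-4)

    def test_identity_slope_gives_one(self):
        c = Constants()
        slope = 2.303 * c.R * c.T / c.F
        assert laviron_alpha_n(slope, c) == pytest.approx(1.0, rel=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.floats(1e-3, 10.0, allow_nan=False))
    def test_product_with_slope_is_constant(self, slope):
        c = Constants()
        assert laviron_alpha_n(slope, c) * slope == pytest.approx(
            2.303 * c.R * c.T / c.F, rel=1e-12
        )

    def test_halving_slope_doubles_alpha_n(self):
        assert laviron_alpha_n(0.05) == pytest.approx(2 * laviron_alpha_n(0.1), rel=1e-12)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(DomainError):
            laviron_alpha_n(0.0)


class TestBardFaulkner:
    @pytest.mark.parametrize(
        "width_mv, alpha",
        [(47.7, 1.0), (90.0, 0.53), (95.4, 0.5)],
    )
    def test_half_width_to_alpha(self, width_mv, alpha):
        assert bard_faulkner_alpha(0.736, 0.736 - width_mv / 1000.0) == pytest.approx(
            alpha, rel=1e-9
        )

    def test_inverted_widths_rejected(self):
        with pytest.raises(DomainError):
            bard_faulkner_alpha(0.7, 0.7)


class TestElectronCount:
    def test_worked_example(self):
        n_float, n_int = electron_count(0.57, 0.53)
        assert n_float == pytest.approx(1.075, abs=1e-3)
        assert n_int == 1

    def test_equal_inputs_give_one(self):
        assert electron_count(0.53, 0.53) == (1.0, 1)

    def test_exact_doubling(self):
        n_float, n_int = electron_count(1.06, 0.53)
        assert (n_float, n_int) == (pytest.approx(2.0, rel=1e-12), 2)

    def test_ties_round_away_from_zero(self):
        assert electron_count(0.75, 0.5)[1] == 2

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(1, 9), st.floats(0.05, 0.1, allow_nan=False))
    def test_scaling_identity(self, k, alpha):
        assert electron_count(k * alpha, alpha)[0] == pytest.approx(k, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            electron_count(-1.0, 0.5)


class TestMechanismReport:
    def test_noiseless_study_reproduces_all_configured_slopes(self, noiseless):
        study = generate_mechanism_study(noiseless)
        rep = mechanism_report(study.ph_series, study.scan_series)
        exp = study.ground_truth.expected
        assert rep.fits["ph"].slope == pytest.approx(exp["ph_slope"], rel=1e-9)
        assert rep.fits["loglog"].slope == pytest.approx(exp["loglog_slope"], rel=1e-9)
        assert rep.fits["ep_logv"].slope == pytest.approx(exp["ep_logv_slope"], rel=1e-9)
        assert rep.control_regime == "mixed"
        assert "ip_sqrtv" in rep.fits  # auxiliary linearity diagnostic

    def test_pure_diffusion_study_classified_as_diffusion(self, noiseless):
        cfg = noiseless.model_copy(update={"ip_power_law": (0.5, 1.5706)})
        study = generate_mechanism_study(cfg)
        rep = mechanism_report(study.ph_series, study.scan_series)
        assert rep.control_regime == "diffusion"

    def test_seeded_noisy_study_concludes_one_electron(self, config):
        study = generate_mechanism_study(config)
        rep = mechanism_report(study.ph_series, study.scan_series)
        assert rep.n_int == 1
        assert rep.proton_coupled is True

    def test_alpha_uses_peak_nearest_reference_scan_rate(self, noiseless):
        study = generate_mechanism_study(noiseless)
        rep = mechanism_report(study.ph_series, study.scan_series)
        # rising-flank half-width is 90 mV by construction -> alpha = 0.53
        assert rep.alpha == pytest.approx(0.53, rel=1e-9)


class TestCoverage:
    def test_ci_coverage_of_law_slopes_is_calibrated(self, config):
        """95% CIs across seeded replicates cover the true slopes 90-99% of
        the time (a check that the noise model and OLS errors agree)."""
        n_rep, cov_ph, cov_ll = 60, 0, 0
        for i in range(n_rep):
            study = generate_mechanism_study(config.with_seed(5000 + i))
            rep = mechanism_report(study.ph_series, study.scan_series)
            lo, hi = rep.fits["ph"].slope_ci(0.95)
            cov_ph += lo <= config.ph_law[0] <= hi
            lo, hi = rep.fits["loglog"].slope_ci(0.95)
            cov_ll += lo <= config.ip_power_law[0] <= hi
        assert 0.90 * n_rep <= cov_ph <= 0.99 * n_rep + 1
        assert 0.90 * n_rep <= cov_ll <= 0.99 * n_rep + 1
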