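"""Electron-transfer mechanism inference from peak behaviour.

The chain mirrors the classical diagnostic workflow for an irreversible
anodic process on a solid electrode:

1. Ep vs pH — a slope of tens of mV per pH unit shows protons participate in
   the electrode reaction (a Nernstian ~59 mV/pH slope indicates equal proton
   and electron numbers).
2. log10(Ip) vs log10(v) — the power-law exponent separates diffusion control
   (0.5) from adsorption control (1.0); intermediate exponents mean a mixed
   regime.
3. Ep vs log10(v) — for an irreversible couple, Laviron's relation makes this
   linear with slope 2.303*R*T/(alpha*n*F), giving the transfer-coefficient x
   electron-number product alpha*n.
4. |Ep - Ep1/2| — at 25 C the irreversible half-peak width equals
   47.7 mV / alpha, giving alpha on its own.
5. n = (alpha*n) / alpha, rounded to the nearest integer, is the electron
   count of the rate-determining oxidation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .voltammetry import Constants, Peak, PeakDetector, Voltammogram

CONTROL_REGIMES = ("diffusion", "mixed", "adsorption")


class DegenerateDesignError(ValueError):
    """Regression design with no variance in the predictor."""


class DomainError(ValueError):
    """Input outside the mathematical domain of a mechanism relation."""


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line with the axes it was fitted on."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    slope_stderr: float
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a reported fit needs >= 3 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        t = stats.t.ppf(0.5 + level / 2.0, self.n_points - 2)
        return (self.slope - t * self.slope_stderr, self.slope + t * self.slope_stderr)

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear(x, y, x_label: str = "x", y_label: str = "y") -> RegressionFit:
    """OLS of y on x.

    A constant y is a legitimate degenerate case (slope 0, r^2 defined as 0
    by convention); a constant x is an error because the slope is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 0.0, n, 0.0, 0.0, x_label, y_label)
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    r2 = float(min(max(res.rvalue**2, 0.0), 1.0))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=n,
        residual_sd=residual_sd,
        slope_stderr=float(res.stderr),
        x_label=x_label,
        y_label=y_label,
    )


@dataclasses.dataclass(frozen=True)
class MechanismReport:
    """Assembled electron-transfer inference."""

    alpha_n: float  # transfer-coefficient x electron-number product
    alpha: float  # transfer coefficient
    n_electrons: float  # alpha_n / alpha, unrounded
    n_int: int  # nearest integer electron count
    control_regime: str  # diffusion | mixed | adsorption
    proton_coupled: bool
    fits: dict[str, RegressionFit]  # ph, loglog, ep_logv, ip_sqrtv

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")
        if not self.alpha_n > 0:
            raise DomainError("alpha_n must be > 0")
        if self.control_regime not in CONTROL_REGIMES:
            raise ValueError(f"unknown control regime {self.control_regime!r}")


# -- individual relations ----------------------------------------------------

PROTON_SLOPE_THRESHOLD_V = 0.020  # |dEp/dpH| >= 20 mV/pH flags proton coupling
CONTROL_TOL = 0.05  # band around the 0.5 / 1.0 anchors


def ph_dependence(
    peaks: Sequence[tuple[float, Peak]],
    threshold_v: float = PROTON_SLOPE_THRESHOLD_V,
) -> tuple[RegressionFit, bool]:
    """Regress Ep on pH; flag proton coupling when |slope| >= threshold."""
    ph = [p for p, _ in peaks]
    if len(set(ph)) < 3:
        raise ValueError("need >= 3 distinct pH values")
    fit = fit_linear(ph, [pk.ep for _, pk in peaks], "pH", "Ep (V)")
    return fit, bool(abs(fit.slope) >= threshold_v)


def scan_rate_analysis(
    peaks: Sequence[tuple[float, Peak]],
) -> tuple[RegressionFit, RegressionFit]:
    """log10(Ip) on log10(v), and Ep (untransformed) on log10(v).

    The second fit feeds Laviron's relation, which is linear in log v with Ep
    itself (not its logarithm) as the response.
    """
    v = np.array([u for u, _ in peaks], dtype=float)
    ip = np.array([pk.ip for _, pk in peaks], dtype=float)
    ep = np.array([pk.ep for _, pk in peaks], dtype=float)
    if np.unique(v).size < 3:
        raise ValueError("need >= 3 distinct scan rates")
    if np.any(v <= 0):
        raise DomainError("scan rates must be > 0")
    if np.any(ip <= 0):
        raise DomainError("peak currents must be > 0 for the log-log fit")
    logv = np.log10(v)
    loglog = fit_linear(logv, np.log10(ip), "log10 v (V/s)", "log10 Ip (uA)")
    ep_logv = fit_linear(logv, ep, "log10 v (V/s)", "Ep (V)")
    return loglog, ep_logv


def classify_control(loglog_slope: float, tol: float = CONTROL_TOL) -> str:
    """Regime from the log Ip - log v exponent: 0.5 diffusion, 1.0 adsorption.

    Boundaries are inclusive toward the pure regimes within ``tol``.
    """
    if not math.isfinite(loglog_slope):
        raise DomainError("slope must be finite")
    if loglog_slope <= 0.5 + tol:
        return "diffusion"
    if loglog_slope >= 1.0 - tol:
        return "adsorption"
    return "mixed"


def laviron_alpha_n(
    ep_logv_slope: float, constants: Constants = Constants()
) -> float:
    """alpha*n from the Ep vs log10(v) slope: 2.303*R*T / (F * slope)."""
    if not ep_logv_slope > 0:
        raise DomainError("Ep vs log v slope must be > 0 for an anodic process")
    c = constants
    return 2.303 * c.R * c.T / (c.F * ep_logv_slope)


def bard_faulkner_alpha(
    ep: float, ep_half: float, constants: Constants = Constants()
) -> float:
    """alpha from the irreversible half-peak width: 47.7 mV / (Ep - Ep1/2)."""
    if not ep > ep_half:
        raise DomainError("Ep must exceed Ep1/2 on an anodic wave")
    return constants.bard_faulkner_mv / (1000.0 * (ep - ep_half))


def electron_count(alpha_n: float, alpha: float) -> tuple[float, int]:
    """Electron number n = alpha_n / alpha (float and nearest integer).

    Ties round away from zero.
    """
    if not (alpha_n > 0 and alpha > 0):
        raise DomainError("alpha_n and alpha must be > 0")
    if not alpha < 1:
        raise DomainError("alpha must be < 1")
    n_float = alpha_n / alpha
    n_int = int(math.floor(n_float + 0.5))  # n_float > 0
    return n_float, n_int


# -- composed analyzer -------------------------------------------------------


class MechanismAnalyzer(BaseEstimator):
    """Full mechanism inference from a pH series and a scan-rate series.

    ``fit`` accepts lists of ``(ph, Voltammogram)`` / ``(scan_rate,
    Voltammogram)`` pairs (peaks are extracted with the configured detector
    settings) or pre-extracted ``(value, Peak)`` pairs. The transfer
    coefficient alpha is computed from the peak measured closest to
    ``reference_scan_rate``.
    """

    def __init__(
        self,
        temperature_k: float = 298.0,
        reference_scan_rate: float = 0.1,
        control_tol: float = CONTROL_TOL,
        proton_threshold_v: float = PROTON_SLOPE_THRESHOLD_V,
        baseline_window: tuple[float, float] | None = None,
        baseline_fraction: float = 0.2,
        parabolic: bool = False,
    ):
        self.temperature_k = temperature_k
        self.reference_scan_rate = reference_scan_rate
        self.control_tol = control_tol
        self.proton_threshold_v = proton_threshold_v
        self.baseline_window = baseline_window
        self.baseline_fraction = baseline_fraction
        self.parabolic = parabolic

    def _peaks(self, series) -> list[tuple[float, Peak]]:
        detector = PeakDetector(
            baseline_window=self.baseline_window,
            baseline_fraction=self.baseline_fraction,
            parabolic=self.parabolic,
        )
        out = []
        for value, obj in series:
            peak = detector.detect(obj) if isinstance(obj, Voltammogram) else obj
            out.append((float(value), peak))
        return out

    def fit(self, ph_series, scan_series):
        constants = Constants(T=self.temperature_k)
        ph_peaks = self._peaks(ph_series)
        scan_peaks = self._peaks(scan_series)

        self.ph_fit_, self.proton_coupled_ = ph_dependence(
            ph_peaks, threshold_v=self.proton_threshold_v
        )
        self.loglog_fit_, self.ep_logv_fit_ = scan_rate_analysis(scan_peaks)
        # Auxiliary linearity check: Ip against sqrt(v).
        v = np.array([u for u, _ in scan_peaks])
        ip = np.array([pk.ip for _, pk in scan_peaks])
        self.ip_sqrtv_fit_ = fit_linear(
            np.sqrt(v), ip, "sqrt(v) (V/s)^1/2", "Ip (uA)"
        )

        self.control_regime_ = classify_control(
            self.loglog_fit_.slope, tol=self.control_tol
        )
        self.alpha_n_ = laviron_alpha_n(self.ep_logv_fit_.slope, constants)
        ref_rate, ref_peak = min(
            scan_peaks, key=lambda item: abs(item[0] - self.reference_scan_rate)
        )
        self.reference_peak_ = ref_peak
        self.reference_scan_rate_ = ref_rate
        self.alpha_ = bard_faulkner_alpha(ref_peak.ep, ref_peak.ep_half, constants)
        self.n_electrons_, self.n_int_ = electron_count(self.alpha_n_, self.alpha_)
        return self

    def report(self) -> MechanismReport:
        return MechanismReport(
            alpha_n=self.alpha_n_,
            alpha=self.alpha_,
            n_electrons=self.n_electrons_,
            n_int=self.n_int_,
            control_regime=self.control_regime_,
            proton_coupled=self.proton_coupled_,
            fits={
                "ph": self.ph_fit_,
                "loglog": self.loglog_fit_,
                "ep_logv": self.ep_logv_fit_,
                "ip_sqrtv": self.ip_sqrtv_fit_,
            },
        )


def mechanism_report(
    ph_series, scan_series, constants: Constants = Constants(), **analyzer_params
) -> MechanismReport:
    """Run the full inference chain and assemble a :class:`MechanismReport`."""
    analyzer = MechanismAnalyzer(temperature_k=constants.T, **analyzer_params)
    return analyzer.fit(ph_series, scan_series).report()
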