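"""Analytical method validation: calibration with LOD/LOQ, precision,
spike recovery, interference and reference-method comparison.

Conventions (ICH-style):

* LOD = 3.3 * sigma_blank / S and LOQ = 10 * sigma_blank / S, where S is the
  calibration slope (sensitivity, uA/uM) and sigma_blank the blank standard
  deviation (falling back to the calibration residual sd when no blank
  replicates are available).
* %RSD uses the sample standard deviation (n - 1 denominator).
* Interference percent change is unsigned: 100 * |dI| / I_reference.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .mechanism import RegressionFit, fit_linear

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


class ValidationInputError(ValueError):
    """Invalid validation-stage input."""


# -- calibration ---------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Fitted calibration line with detection/quantitation limits."""

    slope: float  # uA/uM
    intercept: float  # uA
    r_squared: float
    sigma_blank: float  # uA
    sigma_source: str  # "blank_replicates" | "calibration_residuals"
    lod: float  # uM
    loq: float  # uM
    linear_range: tuple[float, float]  # uM
    n_points: int
    usable: bool  # False when the slope is not positive


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """OLS calibration of peak current against concentration.

    Parameters
    ----------
    blank_sd : float or None
        Standard deviation of blank replicates, in uA. When None the
        residual standard deviation of the fit is used for LOD/LOQ.
    """

    def __init__(self, blank_sd: float | None = None):
        self.blank_sd = blank_sd

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        current = np.asarray(y, dtype=float).reshape(-1)
        if conc.size != current.size:
            raise ValidationInputError("concentration/current length mismatch")
        if np.unique(conc).size < 3:
            raise ValidationInputError("need >= 3 distinct concentrations")
        if np.any(current <= 0):
            raise ValidationInputError("calibration currents must be positive")
        fit = fit_linear(conc, current, "concentration (uM)", "Ip (uA)")

        self.fit_ = fit
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r_squared_ = fit.r_squared
        self.usable_ = fit.slope > 0
        if not self.usable_:
            warnings.warn(
                "non-positive calibration slope: model flagged unusable",
                stacklevel=2,
            )
        if self.blank_sd is not None:
            if self.blank_sd < 0:
                raise ValidationInputError("blank_sd must be >= 0")
            self.sigma_blank_ = float(self.blank_sd)
            self.sigma_source_ = "blank_replicates"
        else:
            self.sigma_blank_ = fit.residual_sd
            self.sigma_source_ = "calibration_residuals"
        if self.usable_:
            self.lod_ = LOD_FACTOR * self.sigma_blank_ / self.slope_
            self.loq_ = LOQ_FACTOR * self.sigma_blank_ / self.slope_
        else:
            self.lod_ = float("nan")
            self.loq_ = float("nan")
        self.linear_range_ = (self.lod_, float(np.max(conc)))
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * conc + self.intercept_

    def quantify(self, current):
        """Invert the calibration: concentration from measured current."""
        i = np.asarray(current, dtype=float)
        return (i - self.intercept_) / self.slope_

    def to_model(self) -> CalibrationModel:
        return CalibrationModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            sigma_blank=self.sigma_blank_,
            sigma_source=self.sigma_source_,
            lod=self.lod_,
            loq=self.loq_,
            linear_range=self.linear_range_,
            n_points=self.fit_.n_points,
            usable=self.usable_,
        )


def fit_calibration(conc, ip, blank_sd: float | None = None) -> CalibrationModel:
    """Functional wrapper over :class:`CalibrationCurve`."""
    return CalibrationCurve(blank_sd=blank_sd).fit(conc, ip).to_model()


# -- recovery & precision ------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RecoveryResult:
    spiked: float  # uM
    mean_measured: float  # uM
    recovery_pct: float  # 100 * mean / spiked
    rsd_pct: float  # 100 * sd / mean (sample sd); 0.0 when n = 1
    n_replicates: int


def recovery(measured, spiked: float) -> RecoveryResult:
    """Spike recovery from replicate measured concentrations."""
    if not spiked > 0:
        raise ValidationInputError("spiked concentration must be > 0")
    m = np.atleast_1d(np.asarray(measured, dtype=float))
    if m.size < 1:
        raise ValidationInputError("need >= 1 replicate")
    mean = float(np.mean(m))
    sd = float(np.std(m, ddof=1)) if m.size > 1 else 0.0
    return RecoveryResult(
        spiked=float(spiked),
        mean_measured=mean,
        recovery_pct=100.0 * mean / spiked,
        rsd_pct=100.0 * sd / mean if mean != 0 else float("inf"),
        n_replicates=int(m.size),
    )


@dataclasses.dataclass(frozen=True)
class PrecisionSummary:
    mode: str  # "intra_day" | "inter_day"
    per_level_rsd: dict[float, float]  # level -> %RSD
    median_rsd: float
    skipped_levels: list[float]


def precision(
    replicate_sets: Mapping[float, Sequence[float]], mode: str = "intra_day"
) -> PrecisionSummary:
    """Per-level %RSD plus the median across levels.

    Levels with fewer than 2 replicates cannot yield a sample sd and are
    skipped with a warning.
    """
    if mode not in ("intra_day", "inter_day"):
        raise ValidationInputError(f"unknown precision mode {mode!r}")
    per_level: dict[float, float] = {}
    skipped: list[float] = []
    for level, values in replicate_sets.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            warnings.warn(
                f"level {level}: fewer than 2 replicates, skipped", stacklevel=2
            )
            skipped.append(float(level))
            continue
        per_level[float(level)] = 100.0 * float(np.std(v, ddof=1)) / float(np.mean(v))
    if not per_level:
        raise ValidationInputError("no level has >= 2 replicates")
    return PrecisionSummary(
        mode=mode,
        per_level_rsd=per_level,
        median_rsd=float(np.median(list(per_level.values()))),
        skipped_levels=skipped,
    )


# -- interference --------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class InterferenceResult:
    interferent_id: str
    interferent_conc: float  # uM
    delta_i: float  # uA, signed (perturbed - reference)
    pct_change: float  # unsigned percent of the reference current


def interference_change(
    reference_current: float,
    perturbed_current: float,
    interferent: str,
    conc: float,
) -> InterferenceResult:
    """Signed signal change and unsigned percent change for one interferent."""
    if not reference_current > 0:
        raise ValidationInputError("reference current must be > 0")
    delta = perturbed_current - reference_current
    return InterferenceResult(
        interferent_id=interferent,
        interferent_conc=float(conc),
        delta_i=float(delta),
        pct_change=100.0 * abs(delta) / reference_current,
    )


@dataclasses.dataclass(frozen=True)
class InterferenceConsistency:
    """Check that printed (dI, %change) pairs share one reference current."""

    reference_current: float  # uA, median of per-row implied references
    implied_references: list[float]
    relative_deviation: list[float]  # |implied/ref - 1| per row
    flagged_rows: list[int]  # rows deviating more than flag_tol
    consistent: bool  # all rows within rel_tol


def interference_consistency(
    table: pd.DataFrame, rel_tol: float = 0.05, flag_tol: float = 0.02
) -> InterferenceConsistency:
    """Back-derive the (unprinted) reference current from each row of an
    interference table (columns ``delta_i_uA, pct_change``) as
    |dI| / (pct/100), and test mutual consistency against the median."""
    missing = {"delta_i_uA", "pct_change"} - set(table.columns)
    if missing:
        raise ValidationInputError(f"missing columns {sorted(missing)}")
    d = table["delta_i_uA"].astype(float).abs()
    p = table["pct_change"].astype(float)
    if (p <= 0).any():
        raise ValidationInputError("percent changes must be > 0 for back-derivation")
    implied = (d / (p / 100.0)).to_numpy()
    ref = float(np.median(implied))
    rel = np.abs(implied / ref - 1.0)
    flagged = [int(i) for i in np.nonzero(rel > flag_tol)[0]]
    return InterferenceConsistency(
        reference_current=ref,
        implied_references=[float(x) for x in implied],
        relative_deviation=[float(x) for x in rel],
        flagged_rows=flagged,
        consistent=bool(np.all(rel <= rel_tol)),
    )


# -- reference-method comparison ------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MethodComparison:
    fit: RegressionFit  # reference regressed on the sensor values
    agreement: bool  # slope in [0.9, 1.1] and r^2 >= 0.99


def compare_methods(test_conc, ref_conc) -> MethodComparison:
    """OLS of the reference method (e.g. GC-MS) on the sensor concentrations."""
    t = np.asarray(test_conc, dtype=float)
    r = np.asarray(ref_conc, dtype=float)
    if t.shape != r.shape:
        raise ValidationInputError("paired series must have equal length")
    if t.size < 3:
        raise ValidationInputError("need >= 3 paired samples")
    fit = fit_linear(t, r, "sensor (uM)", "reference (uM)")
    agreement = bool(0.9 <= fit.slope <= 1.1 and fit.r_squared >= 0.99)
    return MethodComparison(fit=fit, agreement=agreement)
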