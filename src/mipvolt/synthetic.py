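"""Seeded synthetic-data generator emulating the sensor's empirical laws.

The generator is phenomenological: no diffusion equation or Butler-Volmer
kinetics is solved. Each voltammogram is a smooth asymmetric peak on a linear
background, with the peak centre and amplitude placed by the empirical laws
the instrument obeys:

* Ep linear in pH (default slope 0.0567 V/pH),
* log10(Ip) linear in log10(scan rate) (default exponent 0.7677),
* Ep linear in log10(scan rate) (default slope 0.1016 V/decade),
* Ip linear in concentration (calibration sensitivity),

composed additively around the reference condition pH 7, 0.1 V/s, where the
anodic peak sits at 0.736 V. Validation tables (calibration, precision,
recovery, interference, method comparison) are generated directly from the
same laws with multiplicative matrix effects and additive interferent
perturbations.

Every dataset carries its :class:`GroundTruth`, sufficient to compute every
expected analyzer output in closed form, so noiseless generator output is an
exact oracle for the whole pipeline.

Peak shape: a compactly supported Gaussian-like bump, exp(1 - 1/(1 - u^2)),
with independent rising/falling width scales. The rising-flank half-width
(Ep - Ep1/2) is a direct parameter, and the shape is exactly zero in the
baseline window, so baseline fitting and half-height interpolation are exact
on noiseless traces. A true asymmetric Gaussian is available via
``peak_shape="gaussian"`` when realistic tails matter more than exactness.
The potential grid is anchored at the law-predicted peak centre (2 mV step by
default), so noiseless peak extraction is exact rather than
half-a-grid-step accurate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .mechanism import classify_control, electron_count, laviron_alpha_n
from .voltammetry import Constants, Voltammogram, write_voltammogram

# Bump argument at which exp(1 - 1/(1 - u^2)) = 1/2.
_U_HALF = math.sqrt(1.0 - 1.0 / (1.0 + math.log(2.0)))
_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))

# Default sensitivity ties the calibration line to the scan-rate power law:
# at the reference condition (0.1 V/s, 50 uM) the power law's printed
# intercept is reproduced exactly.
_DEFAULT_SENSITIVITY = 10**1.5706 * 0.1**0.7677 / 50.0  # uA/uM


class SyntheticConfig(BaseModel):
    """Study conditions for the generator. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # Empirical laws (slope, intercept)
    ph_law: tuple[float, float] = (0.0567, 1.101)  # V/pH, V
    ip_power_law: tuple[float, float] = (0.7677, 1.5706)  # exponent, log10 uA
    ep_logv_law: tuple[float, float] = (0.1016, 0.7971)  # V/decade, V

    # Peak geometry
    half_width_mv: float = 90.0  # rising-flank Ep - Ep1/2 (alpha = 0.53)
    falling_half_width_mv: float = 55.0  # falling-flank half-width
    peak_shape: Literal["bump", "gaussian"] = "bump"

    # Reference condition the laws are anchored to
    reference_ep: float = 0.736  # V at pH 7, 0.1 V/s
    reference_ph: float = 7.0
    reference_scan_rate: float = 0.1  # V/s
    reference_conc_um: float = 50.0  # uM used in the mechanism studies

    # Calibration / validation design
    calibration_sensitivity: float = _DEFAULT_SENSITIVITY  # uA/uM
    calibration_levels_um: tuple[float, ...] = (2, 10, 25, 40, 55, 70, 75)
    calibration_replicates: int = 3
    recovery_spikes_um: tuple[float, ...] = (25.0, 40.0)
    recovery_replicates: int = 3
    matrix_effect: dict[str, float] = Field(
        default_factory=lambda: {"plasma": 0.95, "urine": 0.96}
    )
    # Interferent perturbations, uA per uM of interferent (synthetic values
    # calibrated to reproduce the published interference magnitudes).
    interference_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "4-MU": 3.7e-4,
            "CMP": -2.5e-4,
            "DSX": -3.9e-4,
            "PPX": -2.4e-4,
        }
    )
    interference_reference_current: float = 0.2311  # uA, 10 uM analyte by DPV
    interferent_levels_um: tuple[float, ...] = (10.0, 50.0, 100.0)
    comparison_levels_um: tuple[float, ...] = (25, 40, 55, 70, 85)
    comparison_law: tuple[float, float] = (0.9972, 1.6067)  # ref = a*test + b
    comparison_sd_um: float = 0.2
    precision_intra_replicates: int = 5
    precision_inter_days: int = 5
    inter_day_rel_sd: float = 0.03

    # Noise model (all >= 0)
    noise_sigma_e: float = 0.002  # V jitter on the peak centre, per trace
    noise_sigma_i: float = 0.01  # uA additive noise per current sample
    ip_rel_sd: float = 0.03  # relative amplitude noise per trace/replicate

    # Acquisition
    grid_step: float = 0.002  # V
    window_before: float = 0.35  # V of sweep before the nominal peak centre
    window_after: float = 0.30  # V after
    background: tuple[float, float] = (0.5, 0.1)  # uA intercept, uA/V slope
    dpv_pulse_amplitude_mv: float = 50.0  # stored as metadata only
    dpv_step_mv: float = 9.918  # stored as metadata only

    seed: int = 0

    def model_post_init(self, __context) -> None:
        for name in ("noise_sigma_e", "noise_sigma_i", "ip_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.half_width_mv <= 0 or self.falling_half_width_mv <= 0:
            raise ValueError("peak widths must be > 0")
        if self.calibration_sensitivity <= 0:
            raise ValueError("calibration_sensitivity must be > 0")

    def noiseless(self) -> "SyntheticConfig":
        """Copy with every noise term set to zero."""
        return self.model_copy(
            update={
                "noise_sigma_e": 0.0,
                "noise_sigma_i": 0.0,
                "ip_rel_sd": 0.0,
                "comparison_sd_um": 0.0,
                "inter_day_rel_sd": 0.0,
            }
        )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return self.model_copy(update={"seed": int(seed)})


# -- closed-form laws ----------------------------------------------------------


def peak_potential(config: SyntheticConfig, ph: float, scan_rate: float) -> float:
    """Law-predicted Ep: pH and log-v dependences composed additively around
    the reference condition."""
    return (
        config.reference_ep
        + config.ph_law[0] * (ph - config.reference_ph)
        + config.ep_logv_law[0]
        * (math.log10(scan_rate) - math.log10(config.reference_scan_rate))
    )


def peak_current(config: SyntheticConfig, scan_rate: float, conc: float) -> float:
    """Law-predicted Ip: linear in concentration, power law in scan rate."""
    return (
        config.calibration_sensitivity
        * conc
        * (scan_rate / config.reference_scan_rate) ** config.ip_power_law[0]
    )


def _shape(x: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Unit-amplitude asymmetric peak profile centred at x = 0."""
    hw = config.half_width_mv / 1000.0
    fw = config.falling_half_width_mv / 1000.0
    if config.peak_shape == "bump":
        l_rise, l_fall = hw / _U_HALF, fw / _U_HALF
        u = np.where(x < 0, x / l_rise, x / l_fall)
        out = np.zeros_like(u)
        m = np.abs(u) < 1.0
        out[m] = np.exp(1.0 - 1.0 / (1.0 - u[m] ** 2))
        return out
    s_rise, s_fall = hw / _SQRT_2LN2, fw / _SQRT_2LN2
    s = np.where(x < 0, s_rise, s_fall)
    return np.exp(-0.5 * (x / s) ** 2)


@dataclasses.dataclass
class GroundTruth:
    """Exact generating parameters and closed-form expected outputs."""

    laws: dict
    traces: list[dict]
    expected: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# -- trace generation ----------------------------------------------------------


def generate_voltammogram(
    config: SyntheticConfig,
    ph: float,
    scan_rate: float,
    conc: float | None = None,
    seed_offset: int = 0,
    technique: str = "CV",
) -> tuple[Voltammogram, dict]:
    """One synthetic trace plus its per-trace ground truth.

    Fully determined by ``(config.seed, seed_offset)``; the potential grid is
    anchored at the law-predicted peak centre.
    """
    if scan_rate <= 0:
        raise ValueError("scan_rate must be > 0")
    if conc is not None and conc < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng([abs(int(config.seed)), abs(int(seed_offset))])

    ep_law = peak_potential(config, ph, scan_rate)
    ip_law = peak_current(config, scan_rate, conc) if conc else 0.0
    center = ep_law + rng.normal(0.0, config.noise_sigma_e)
    amp = ip_law * (1.0 + rng.normal(0.0, config.ip_rel_sd))

    step = config.grid_step
    k0 = -int(round(config.window_before / step))
    k1 = int(round(config.window_after / step))
    potential = ep_law + step * np.arange(k0, k1 + 1, dtype=float)
    bg_b, bg_m = config.background
    current = bg_b + bg_m * potential + amp * _shape(potential - center, config)
    if config.noise_sigma_i > 0:
        current = current + rng.normal(0.0, config.noise_sigma_i, potential.size)

    vg = Voltammogram(
        potential=potential,
        current=current,
        technique=technique,
        scan_rate=scan_rate,
        ph=ph,
        concentration=conc,
        label=f"synthetic seed={config.seed}/{seed_offset}",
    )
    truth = {
        "ph": ph,
        "scan_rate": scan_rate,
        "conc_um": conc,
        "ep_law": ep_law,
        "ip_law": ip_law,
        "ep_true": center,
        "ip_true": amp,
    }
    return vg, truth


# -- mechanism study -----------------------------------------------------------


@dataclasses.dataclass
class MechanismStudy:
    ph_series: list[tuple[float, Voltammogram]]
    scan_series: list[tuple[float, Voltammogram]]
    ground_truth: GroundTruth


def expected_mechanism(
    config: SyntheticConfig, constants: Constants = Constants()
) -> dict:
    """Closed-form analyzer outputs implied by the configured laws."""
    exponent = config.ip_power_law[0]
    alpha_n = laviron_alpha_n(config.ep_logv_law[0], constants)
    alpha = constants.bard_faulkner_mv / config.half_width_mv
    n_float, n_int = electron_count(alpha_n, alpha)
    s_conc = config.calibration_sensitivity * config.reference_conc_um
    loglog_intercept = math.log10(s_conc) - exponent * math.log10(
        config.reference_scan_rate
    )
    return {
        "ph_slope": config.ph_law[0],
        "loglog_slope": exponent,
        "loglog_intercept": loglog_intercept,
        "ep_logv_slope": config.ep_logv_law[0],
        "alpha_n": alpha_n,
        "alpha": alpha,
        "n_electrons": n_float,
        "n_int": n_int,
        "control_regime": classify_control(exponent),
        "proton_coupled": abs(config.ph_law[0]) >= 0.020,
    }


def generate_mechanism_study(config: SyntheticConfig) -> MechanismStudy:
    """pH series (pH 3-9, step 1, at the reference scan rate) and scan-rate
    series (log-spaced 0.05-1.0 V/s at the reference pH), with ground truth."""
    ph_grid = np.arange(3.0, 10.0, 1.0)
    scan_grid = np.logspace(math.log10(0.05), math.log10(1.0), 6)

    ph_series, scan_series, traces = [], [], []
    for k, ph in enumerate(ph_grid):
        vg, truth = generate_voltammogram(
            config,
            ph=float(ph),
            scan_rate=config.reference_scan_rate,
            conc=config.reference_conc_um,
            seed_offset=k,
            technique="DPV",
        )
        truth["series"] = "ph"
        ph_series.append((float(ph), vg))
        traces.append(truth)
    for k, v in enumerate(scan_grid):
        vg, truth = generate_voltammogram(
            config,
            ph=config.reference_ph,
            scan_rate=float(v),
            conc=config.reference_conc_um,
            seed_offset=100 + k,
            technique="CV",
        )
        truth["series"] = "scan"
        scan_series.append((float(v), vg))
        traces.append(truth)

    gt = GroundTruth(
        laws=_law_dict(config),
        traces=traces,
        expected=expected_mechanism(config),
    )
    return MechanismStudy(ph_series=ph_series, scan_series=scan_series, ground_truth=gt)


def _law_dict(config: SyntheticConfig) -> dict:
    return {
        "ph_law": list(config.ph_law),
        "ip_power_law": list(config.ip_power_law),
        "ep_logv_law": list(config.ep_logv_law),
        "half_width_mv": config.half_width_mv,
        "calibration_sensitivity": config.calibration_sensitivity,
        "matrix_effect": dict(config.matrix_effect),
        "interference_coefficients": dict(config.interference_coefficients),
        "interference_reference_current": config.interference_reference_current,
        "comparison_law": list(config.comparison_law),
        "seed": config.seed,
    }


# -- validation study ----------------------------------------------------------


@dataclasses.dataclass
class ValidationStudy:
    calibration: pd.DataFrame  # level_uM, replicate, current_uA
    precision_intra: pd.DataFrame  # level_uM, replicate, current_uA
    precision_inter: pd.DataFrame  # level_uM, replicate (day), current_uA
    recovery: pd.DataFrame  # matrix, spiked_uM, measured_uM
    interference: pd.DataFrame  # interferent, conc_uM, current_uA
    comparison: pd.DataFrame  # sample, test_uM, ref_uM
    ground_truth: GroundTruth


def generate_validation_study(config: SyntheticConfig) -> ValidationStudy:
    """Calibration, precision, recovery, interference and comparison tables
    drawn from the configured laws, with ground truth attached.

    The interference table includes an ``interferent = "none"`` row carrying
    the unperturbed reference current.
    """
    s = config.calibration_sensitivity

    rng = np.random.default_rng([abs(int(config.seed)), 10_000])
    cal_rows = []
    for level in config.calibration_levels_um:
        for rep in range(1, config.calibration_replicates + 1):
            i = s * level * (1.0 + rng.normal(0.0, config.ip_rel_sd)) + rng.normal(
                0.0, config.noise_sigma_i
            )
            cal_rows.append((level, rep, i))
    calibration = pd.DataFrame(cal_rows, columns=["level_uM", "replicate", "current_uA"])

    rng = np.random.default_rng([abs(int(config.seed)), 20_000])
    rec_rows = []
    for matrix, factor in config.matrix_effect.items():
        for spike in config.recovery_spikes_um:
            for _ in range(config.recovery_replicates):
                measured = spike * factor * (1.0 + rng.normal(0.0, config.ip_rel_sd))
                rec_rows.append((matrix, spike, measured))
    recovery = pd.DataFrame(rec_rows, columns=["matrix", "spiked_uM", "measured_uM"])

    rng = np.random.default_rng([abs(int(config.seed)), 30_000])
    ref = config.interference_reference_current
    int_rows = [("none", 0.0, ref)]
    for interferent, coeff in config.interference_coefficients.items():
        for conc in config.interferent_levels_um:
            delta = coeff * conc * (1.0 + rng.normal(0.0, config.ip_rel_sd))
            int_rows.append((interferent, conc, ref + delta))
    interference = pd.DataFrame(int_rows, columns=["interferent", "conc_uM", "current_uA"])

    rng = np.random.default_rng([abs(int(config.seed)), 40_000])
    a, b = config.comparison_law
    cmp_rows = [
        (k + 1, t, a * t + b + rng.normal(0.0, config.comparison_sd_um))
        for k, t in enumerate(config.comparison_levels_um)
    ]
    comparison = pd.DataFrame(cmp_rows, columns=["sample", "test_uM", "ref_uM"])

    rng = np.random.default_rng([abs(int(config.seed)), 50_000])
    intra_rows, inter_rows = [], []
    for level in config.calibration_levels_um:
        for rep in range(1, config.precision_intra_replicates + 1):
            intra_rows.append(
                (level, rep, s * level * (1.0 + rng.normal(0.0, config.ip_rel_sd)))
            )
        for day in range(1, config.precision_inter_days + 1):
            day_factor = 1.0 + rng.normal(0.0, config.inter_day_rel_sd)
            inter_rows.append(
                (
                    level,
                    day,
                    s * level * day_factor * (1.0 + rng.normal(0.0, config.ip_rel_sd)),
                )
            )
    precision_intra = pd.DataFrame(
        intra_rows, columns=["level_uM", "replicate", "current_uA"]
    )
    precision_inter = pd.DataFrame(
        inter_rows, columns=["level_uM", "replicate", "current_uA"]
    )

    max_pct = max(
        100.0 * abs(c) * max(config.interferent_levels_um) / ref
        for c in config.interference_coefficients.values()
    )
    expected = {
        "calibration_slope": s,
        "calibration_intercept": 0.0,
        "calibration_r_squared": 1.0,
        "recovery_pct": {m: 100.0 * f for m, f in config.matrix_effect.items()},
        "comparison_slope": a,
        "comparison_intercept": b,
        "interference_reference_current": ref,
        "max_interference_pct": max_pct,
    }
    gt = GroundTruth(laws=_law_dict(config), traces=[], expected=expected)
    return ValidationStudy(
        calibration=calibration,
        precision_intra=precision_intra,
        precision_inter=precision_inter,
        recovery=recovery,
        interference=interference,
        comparison=comparison,
        ground_truth=gt,
    )


# -- disk I/O ------------------------------------------------------------------


def write_mechanism_study(study: MechanismStudy, outdir: str | Path) -> Path:
    """Write traces, a manifest and the ground truth under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for series, pairs in (("ph", study.ph_series), ("scan", study.scan_series)):
        for k, (value, vg) in enumerate(pairs):
            name = f"{series}_{k:02d}.csv"
            write_voltammogram(vg, outdir / name)
            manifest.append(
                {
                    "file": name,
                    "series": series,
                    "technique": vg.technique,
                    "scan_rate_V_s": vg.scan_rate,
                    "ph": vg.ph,
                    "conc_uM": vg.concentration,
                }
            )
    pd.DataFrame(manifest).to_csv(
        outdir / "manifest.csv", index=False, float_format="%.12g"
    )
    (outdir / "ground_truth.json").write_text(study.ground_truth.to_json())
    return outdir


def load_mechanism_study(
    indir: str | Path,
) -> tuple[list[tuple[float, Voltammogram]], list[tuple[float, Voltammogram]]]:
    """Read back a mechanism-study directory written by
    :func:`write_mechanism_study` (or hand-assembled in the same layout)."""
    from .voltammetry import read_voltammogram

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    ph_series, scan_series = [], []
    for row in manifest.itertuples(index=False):
        vg = read_voltammogram(
            indir / row.file,
            technique=row.technique,
            scan_rate=float(row.scan_rate_V_s),
            ph=float(row.ph),
            concentration=float(row.conc_uM) if pd.notna(row.conc_uM) else None,
        )
        if row.series == "ph":
            ph_series.append((float(row.ph), vg))
        else:
            scan_series.append((float(row.scan_rate_V_s), vg))
    return ph_series, scan_series


def write_validation_study(study: ValidationStudy, outdir: str | Path) -> Path:
    """Write the validation tables and ground truth under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "calibration.csv": study.calibration,
        "precision_intra.csv": study.precision_intra,
        "precision_inter.csv": study.precision_inter,
        "recovery.csv": study.recovery,
        "interference.csv": study.interference,
        "comparison.csv": study.comparison,
    }
    for name, df in frames.items():
        df.to_csv(outdir / name, index=False, float_format="%.12g")
    (outdir / "ground_truth.json").write_text(study.ground_truth.to_json())
    return outdir
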