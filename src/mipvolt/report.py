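"""Schema-versioned JSON report aggregating pipeline stage outputs.

The pydantic models below are the shipped schema (exportable as JSON Schema
via :func:`report_json_schema`). Numbers are serialized at full precision;
display-rounded strings live in dedicated ``display`` maps so internal values
are never rounded.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict

from . import __version__
from .mechanism import MechanismReport, RegressionFit
from .screening import RatioCandidate, ScreeningResult
from .validation import (
    CalibrationModel,
    InterferenceResult,
    MethodComparison,
    PrecisionSummary,
    RecoveryResult,
)

SCHEMA_VERSION = "1.0"


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RegressionFitBlock(_Model):
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    slope_stderr: float
    x_label: str
    y_label: str

    @classmethod
    def from_fit(cls, fit: RegressionFit) -> "RegressionFitBlock":
        return cls(**fit.__dict__)


class MechanismBlock(_Model):
    alpha_n: float
    alpha: float
    n_electrons: float
    n_int: int
    control_regime: str
    proton_coupled: bool
    fits: dict[str, RegressionFitBlock]
    display: dict[str, str]


class ScreeningBlock(_Model):
    delta_e: dict[str, float]
    ranking: list[str]
    selected_monomer: str
    units: str
    selected_ratio: Optional[tuple[int, int]] = None
    ratio_score: Optional[float] = None


class CalibrationBlock(_Model):
    slope: float
    intercept: float
    r_squared: float
    sigma_blank: float
    sigma_source: str
    lod: Optional[float]
    loq: Optional[float]
    linear_range: tuple[Optional[float], float]
    n_points: int
    usable: bool
    display: dict[str, str]


class RecoveryBlock(_Model):
    matrix: str
    spiked: float
    mean_measured: float
    recovery_pct: float
    rsd_pct: float
    n_replicates: int


class PrecisionBlock(_Model):
    mode: str
    per_level_rsd: dict[str, float]
    median_rsd: float
    skipped_levels: list[float]


class InterferenceBlock(_Model):
    interferent_id: str
    interferent_conc: float
    delta_i: float
    pct_change: float


class ComparisonBlock(_Model):
    fit: RegressionFitBlock
    agreement: bool


class ValidationBlock(_Model):
    recovery: list[RecoveryBlock] = []
    precision: list[PrecisionBlock] = []
    interference: list[InterferenceBlock] = []
    max_interference_pct: Optional[float] = None
    comparison: Optional[ComparisonBlock] = None
    display: dict[str, str] = {}


class ReportMeta(_Model):
    package: str = "mipvolt"
    version: str = __version__
    seed: Optional[int] = None


class Report(_Model):
    """Top-level report: at least one stage block must be present."""

    schema_version: str = SCHEMA_VERSION
    meta: ReportMeta = ReportMeta()
    config: dict = {}
    mechanism: Optional[MechanismBlock] = None
    screening: Optional[ScreeningBlock] = None
    calibration: Optional[CalibrationBlock] = None
    validation: Optional[ValidationBlock] = None

    def blocks(self) -> dict[str, BaseModel]:
        out = {}
        for name in ("mechanism", "screening", "calibration", "validation"):
            block = getattr(self, name)
            if block is not None:
                out[name] = block
        return out


# -- block constructors ----------------------------------------------------------


def mechanism_block(report: MechanismReport) -> MechanismBlock:
    return MechanismBlock(
        alpha_n=report.alpha_n,
        alpha=report.alpha,
        n_electrons=report.n_electrons,
        n_int=report.n_int,
        control_regime=report.control_regime,
        proton_coupled=report.proton_coupled,
        fits={k: RegressionFitBlock.from_fit(f) for k, f in report.fits.items()},
        display={
            "alpha_n": f"{round_sig(report.alpha_n, 4)}",
            "alpha": f"{round_sig(report.alpha, 4)}",
            "n_electrons": f"{round_sig(report.n_electrons, 4)}",
        },
    )


def screening_block(
    result: ScreeningResult,
    units: str = "unspecified",
    ratio: RatioCandidate | None = None,
) -> ScreeningBlock:
    return ScreeningBlock(
        delta_e=result.delta_e,
        ranking=result.ranking,
        selected_monomer=result.selected_monomer,
        units=units,
        selected_ratio=ratio.ratio if ratio is not None else None,
        ratio_score=ratio.score if ratio is not None else None,
    )


def calibration_block(model: CalibrationModel) -> CalibrationBlock:
    lod = model.lod if math.isfinite(model.lod) else None
    loq = model.loq if math.isfinite(model.loq) else None
    lo = model.linear_range[0]
    return CalibrationBlock(
        slope=model.slope,
        intercept=model.intercept,
        r_squared=model.r_squared,
        sigma_blank=model.sigma_blank,
        sigma_source=model.sigma_source,
        lod=lod,
        loq=loq,
        linear_range=(lo if math.isfinite(lo) else None, model.linear_range[1]),
        n_points=model.n_points,
        usable=model.usable,
        display={
            "lod_uM": f"{round_sig(lod, 3)}" if lod is not None else "n/a",
            "loq_uM": f"{round_sig(loq, 3)}" if loq is not None else "n/a",
            "slope_uA_per_uM": f"{round_sig(model.slope, 4)}",
        },
    )


def validation_block(
    recoveries: list[tuple[str, RecoveryResult]] = (),
    precisions: list[PrecisionSummary] = (),
    interferences: list[InterferenceResult] = (),
    comparison: MethodComparison | None = None,
) -> ValidationBlock:
    rec = [
        RecoveryBlock(
            matrix=matrix,
            spiked=r.spiked,
            mean_measured=r.mean_measured,
            recovery_pct=r.recovery_pct,
            rsd_pct=r.rsd_pct,
            n_replicates=r.n_replicates,
        )
        for matrix, r in recoveries
    ]
    prec = [
        PrecisionBlock(
            mode=p.mode,
            per_level_rsd={f"{k:g}": v for k, v in p.per_level_rsd.items()},
            median_rsd=p.median_rsd,
            skipped_levels=p.skipped_levels,
        )
        for p in precisions
    ]
    intf = [
        InterferenceBlock(
            interferent_id=i.interferent_id,
            interferent_conc=i.interferent_conc,
            delta_i=i.delta_i,
            pct_change=i.pct_change,
        )
        for i in interferences
    ]
    display = {}
    for matrix, r in recoveries:
        display[f"recovery_{matrix}_{r.spiked:g}uM_pct"] = f"{r.recovery_pct:.2f}"
    max_pct = max((i.pct_change for i in intf), default=None)
    if max_pct is not None:
        display["max_interference_pct"] = f"{max_pct:.2f}"
    return ValidationBlock(
        recovery=rec,
        precision=prec,
        interference=intf,
        max_interference_pct=max_pct,
        comparison=(
            ComparisonBlock(
                fit=RegressionFitBlock.from_fit(comparison.fit),
                agreement=comparison.agreement,
            )
            if comparison is not None
            else None
        ),
        display=display,
    )


# -- I/O ---------------------------------------------------------------------------


def write_report(report: Report, path: str | Path) -> Path:
    """Serialize a validated report; at least one stage block is required."""
    if not report.blocks():
        raise ValueError("report must carry at least one stage block")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(report.model_dump_json(indent=2) + "\n", encoding="utf-8")
    return path


def read_report(path: str | Path) -> Report:
    return Report.model_validate_json(Path(path).read_text(encoding="utf-8"))


def report_json_schema() -> dict:
    """The report schema as JSON Schema (generated from the pydantic model)."""
    return Report.model_json_schema()
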