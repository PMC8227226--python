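"""Voltammogram container, CSV I/O and anodic-peak extraction.

A voltammogram is a single potential sweep: potential (V vs Ag/AgCl) against
current (uA), tagged with the technique (CV or DPV), scan rate, medium pH and
analyte concentration. Peak extraction fits a straight baseline over a
pre-peak window, subtracts it, and reports the anodic peak potential Ep, the
baseline-corrected peak current Ip and the rising-flank half-peak potential
Ep1/2 (potential where the corrected current first reaches Ip/2), the three
descriptors every downstream analysis consumes.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

CSV_HEADER = ("potential_V", "current_uA")

TECHNIQUES = ("CV", "DPV")


class VoltammetryError(ValueError):
    """Invalid voltammetric input (malformed file, bad metadata, bad trace)."""


class PeakNotFoundError(VoltammetryError):
    """No interior anodic peak could be extracted from the trace."""


@dataclasses.dataclass(frozen=True)
class Constants:
    """Physical constants used by the electron-transfer relations.

    R and F are kept exactly as conventionally used with these relations
    (F = 96,480 C/mol); T defaults to 298 K. ``bard_faulkner_mv`` is the
    47.7 mV numerator of the irreversible half-peak-width relation at 25 C.
    """

    R: float = 8.314  # J K^-1 mol^-1
    T: float = 298.0  # K
    F: float = 96480.0  # C mol^-1
    bard_faulkner_mv: float = 47.7  # mV

    def __post_init__(self) -> None:
        for name in ("R", "T", "F", "bard_faulkner_mv"):
            if not getattr(self, name) > 0:
                raise VoltammetryError(f"constant {name} must be > 0")


@dataclasses.dataclass
class Voltammogram:
    """One potential/current trace plus its experimental context."""

    potential: np.ndarray  # V, strictly increasing after normalization
    current: np.ndarray  # uA
    technique: str = "CV"
    scan_rate: float | None = None  # V/s
    ph: float | None = None
    concentration: float | None = None  # uM; None for blanks
    label: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.current, dtype=float)
        if e.ndim != 1 or i.ndim != 1:
            raise VoltammetryError("potential and current must be 1-D series")
        if e.size != i.size:
            raise VoltammetryError(
                f"length mismatch: {e.size} potentials vs {i.size} currents"
            )
        if e.size < 8:
            raise VoltammetryError(f"trace too short: {e.size} points (need >= 8)")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(i))):
            raise VoltammetryError("non-finite values in trace")
        # Normalize to increasing potential (anodic sweep orientation).
        if e[0] > e[-1]:
            e, i = e[::-1].copy(), i[::-1].copy()
        if not np.all(np.diff(e) > 0):
            raise VoltammetryError("potential series must be strictly monotone")
        self.potential, self.current = e, i
        if self.technique not in TECHNIQUES:
            raise VoltammetryError(f"unknown technique {self.technique!r}")
        if self.scan_rate is not None and not self.scan_rate > 0:
            raise VoltammetryError("scan_rate must be > 0")
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            raise VoltammetryError("pH must lie in [0, 14]")

    def __len__(self) -> int:
        return self.potential.size


@dataclasses.dataclass(frozen=True)
class Peak:
    """Extracted anodic-peak descriptors (all baseline-corrected)."""

    ep: float  # V, peak potential
    ip: float  # uA, corrected peak current
    ep_half: float  # V, rising-flank half-height potential Ep1/2
    baseline_slope: float  # uA/V of the subtracted background
    baseline_intercept: float  # uA

    def __post_init__(self) -> None:
        if not self.ip > 0:
            raise PeakNotFoundError("peak current must be > 0")
        if not self.ep_half < self.ep:
            raise PeakNotFoundError("Ep1/2 must precede Ep on the rising flank")

    @property
    def half_peak_width(self) -> float:
        """Ep - Ep1/2 in volts (the irreversible-wave width descriptor)."""
        return self.ep - self.ep_half


def read_voltammogram(path: str | Path, **metadata) -> Voltammogram:
    """Read a two-column ``potential_V,current_uA`` CSV into a Voltammogram.

    Metadata (technique, scan_rate, ph, concentration, label) is supplied by
    the caller; it is deliberately not stored in the CSV. Malformed numeric
    cells raise a parse error naming the offending line.
    """
    path = Path(path)
    potentials: list[float] = []
    currents: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise VoltammetryError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != CSV_HEADER:
            raise VoltammetryError(
                f"{path}: expected header {','.join(CSV_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise VoltammetryError(f"{path}: line {lineno}: expected 2 columns")
            try:
                potentials.append(float(row[0]))
                currents.append(float(row[1]))
            except ValueError:
                raise VoltammetryError(
                    f"{path}: line {lineno}: non-numeric value in {row!r}"
                ) from None
    return Voltammogram(np.array(potentials), np.array(currents), **metadata)


def write_voltammogram(vg: Voltammogram, path: str | Path) -> None:
    """Write the trace as a ``potential_V,current_uA`` CSV (full precision)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for e, i in zip(vg.potential, vg.current):
            writer.writerow([repr(float(e)), repr(float(i))])


class PeakDetector(BaseEstimator):
    """Anodic-peak extractor with linear baseline subtraction.

    Parameters
    ----------
    baseline_window : (float, float) or None
        Potential interval used to fit the straight background. Must lie
        inside the trace and precede the peak. When None, the first
        ``baseline_fraction`` of the sweep is used.
    baseline_fraction : float
        Fraction of the sweep used for the default baseline window.
    parabolic : bool
        When True, refine Ep/Ip with a three-point parabola through the
        grid maximum. Off by default so results are tied to the raw grid.
    """

    def __init__(
        self,
        baseline_window: tuple[float, float] | None = None,
        baseline_fraction: float = 0.2,
        parabolic: bool = False,
    ):
        self.baseline_window = baseline_window
        self.baseline_fraction = baseline_fraction
        self.parabolic = parabolic

    def _window(self, e: np.ndarray) -> tuple[float, float]:
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
        else:
            if not 0 < self.baseline_fraction < 1:
                raise VoltammetryError("baseline_fraction must be in (0, 1)")
            lo = e[0]
            hi = e[0] + self.baseline_fraction * (e[-1] - e[0])
        if lo >= hi:
            raise VoltammetryError("empty baseline window")
        if lo < e[0] - 1e-12 or hi > e[-1] + 1e-12:
            raise VoltammetryError("baseline window outside the trace range")
        return lo, hi

    def detect(self, vg: Voltammogram) -> Peak:
        """Extract (Ep, Ip, Ep1/2) from one trace."""
        e, i = vg.potential, vg.current
        lo, hi = self._window(e)
        mask = (e >= lo) & (e <= hi)
        if mask.sum() < 2:
            raise VoltammetryError("baseline window contains < 2 samples")
        slope, intercept = np.polyfit(e[mask], i[mask], 1)
        corrected = i - (slope * e + intercept)

        idx = int(np.argmax(corrected))
        if idx == 0 or idx == len(e) - 1:
            raise PeakNotFoundError(
                "corrected maximum sits on the sweep boundary: no interior peak"
            )
        ip = float(corrected[idx])
        ep = float(e[idx])
        if ip <= 0:
            raise PeakNotFoundError("corrected peak current is not positive")
        if self.parabolic:
            ep, ip = _parabolic_vertex(e, corrected, idx)

        ep_half = _rising_half_crossing(e, corrected, idx, ip / 2.0)
        return Peak(
            ep=ep,
            ip=ip,
            ep_half=ep_half,
            baseline_slope=float(slope),
            baseline_intercept=float(intercept),
        )

    def detect_many(self, vgs: Sequence[Voltammogram]) -> list[Peak]:
        return [self.detect(vg) for vg in vgs]


def _parabolic_vertex(e: np.ndarray, c: np.ndarray, idx: int) -> tuple[float, float]:
    """Vertex of the parabola through the three samples around the maximum."""
    x0, x1, x2 = e[idx - 1 : idx + 2]
    y0, y1, y2 = c[idx - 1 : idx + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; keep the grid values
        return float(e[idx]), float(c[idx])
    xv = -b / (2 * a)
    cc = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + cc)


def _rising_half_crossing(
    e: np.ndarray, c: np.ndarray, peak_idx: int, half: float
) -> float:
    """Potential where the corrected current first crosses ``half`` on the
    rising flank, linearly interpolated between the bracketing samples."""
    for j in range(peak_idx - 1, -1, -1):
        if c[j] <= half:
            if c[j + 1] == c[j]:
                return float(e[j])
            t = (half - c[j]) / (c[j + 1] - c[j])
            return float(e[j] + t * (e[j + 1] - e[j]))
    raise PeakNotFoundError(
        "corrected current never falls below half height on the rising flank"
    )


def detect_peak(
    vg: Voltammogram,
    baseline_window: tuple[float, float] | None = None,
    baseline_fraction: float = 0.2,
    parabolic: bool = False,
) -> Peak:
    """Functional wrapper over :class:`PeakDetector`."""
    return PeakDetector(
        baseline_window=baseline_window,
        baseline_fraction=baseline_fraction,
        parabolic=parabolic,
    ).detect(vg)
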