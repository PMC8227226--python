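"""Functional-monomer screening for molecular imprinting.

Given total energies of the template, each candidate monomer, and the
pre-polymerisation template-monomer complex (all from external quantum
chemistry; this module never runs any), the binding energy is

    dE = E(complex) - E(template) - sum E(monomer)

More negative dE means a more stable complex, hence better imprinting.
A second, independent selection chooses the template:monomer stoichiometry
with the lowest complex energy from a ratio scan.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
from sklearn.base import BaseEstimator


class ScreeningError(ValueError):
    """Invalid screening input."""


@dataclasses.dataclass(frozen=True)
class EnergyRecord:
    """Per-monomer energy triple; units are passed through, never converted."""

    monomer_id: str
    e_complex: float
    e_template: float
    e_monomer: float  # pre-summed when several monomer units are involved
    units: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("e_complex", "e_template", "e_monomer"):
            if not math.isfinite(getattr(self, name)):
                raise ScreeningError(f"{self.monomer_id}: non-finite {name}")


@dataclasses.dataclass(frozen=True)
class ScreeningResult:
    delta_e: dict[str, float]  # monomer_id -> binding energy
    ranking: list[str]  # ascending dE: most negative (best) first
    selected_monomer: str


@dataclasses.dataclass(frozen=True)
class RatioCandidate:
    """One template:monomer stoichiometry and its complex-energy score."""

    ratio: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        if self.ratio[0] < 1 or self.ratio[1] < 1:
            raise ScreeningError("ratio components must be >= 1")
        if not math.isfinite(self.score):
            raise ScreeningError("ratio score must be finite")


def binding_energy(record: EnergyRecord) -> float:
    """dE = E(complex) - E(template) - sum E(monomer), input precision kept."""
    return record.e_complex - record.e_template - record.e_monomer


def screen_monomers(records: Sequence[EnergyRecord]) -> ScreeningResult:
    """Rank candidates by binding energy (ascending) and select the best.

    Ties have no physical basis and are broken lexicographically by
    monomer id, with a warning.
    """
    if len(records) == 0:
        raise ScreeningError("no energy records supplied")
    ids = [r.monomer_id for r in records]
    if len(set(ids)) != len(ids):
        raise ScreeningError("duplicate monomer ids in energy table")
    delta = {r.monomer_id: binding_energy(r) for r in records}
    values = list(delta.values())
    if len(set(values)) != len(values):
        warnings.warn(
            "tied binding energies: ranking ties broken lexicographically",
            stacklevel=2,
        )
    ranking = sorted(delta, key=lambda m: (delta[m], m))
    return ScreeningResult(delta_e=delta, ranking=ranking, selected_monomer=ranking[0])


def select_ratio(candidates: Sequence[RatioCandidate]) -> RatioCandidate:
    """Pick the stoichiometry with the lowest (most stable) complex energy."""
    if len(candidates) == 0:
        raise ScreeningError("no ratio candidates supplied")
    scores = [c.score for c in candidates]
    if len(set(scores)) != len(scores):
        warnings.warn("tied ratio scores: tie broken by ratio order", stacklevel=2)
    return min(candidates, key=lambda c: (c.score, c.ratio))


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read a monomer energy CSV.

    Required columns: ``monomer, e_complex, e_template`` plus either a single
    pre-summed ``e_monomer`` column or several ``e_monomer_*`` columns that
    are summed. An optional ``units`` column is passed through.
    """
    df = pd.read_csv(path)
    required = {"monomer", "e_complex", "e_template"}
    missing = required - set(df.columns)
    if missing:
        raise ScreeningError(f"{path}: missing columns {sorted(missing)}")
    if "e_monomer" in df.columns:
        monomer_energy = df["e_monomer"].astype(float)
    else:
        parts = [c for c in df.columns if c.startswith("e_monomer_")]
        if not parts:
            raise ScreeningError(f"{path}: no e_monomer column(s)")
        monomer_energy = df[parts].astype(float).sum(axis=1)
    units = df["units"] if "units" in df.columns else None
    return [
        EnergyRecord(
            monomer_id=str(row.monomer),
            e_complex=float(row.e_complex),
            e_template=float(row.e_template),
            e_monomer=float(monomer_energy.iloc[i]),
            units=str(units.iloc[i]) if units is not None else "unspecified",
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def read_ratio_scan(path: str | Path) -> list[RatioCandidate]:
    """Read a ``t_count,m_count,score`` stoichiometry-scan CSV."""
    df = pd.read_csv(path)
    missing = {"t_count", "m_count", "score"} - set(df.columns)
    if missing:
        raise ScreeningError(f"{path}: missing columns {sorted(missing)}")
    return [
        RatioCandidate(ratio=(int(r.t_count), int(r.m_count)), score=float(r.score))
        for r in df.itertuples(index=False)
    ]


class MonomerScreener(BaseEstimator):
    """Estimator wrapper around :func:`screen_monomers`.

    ``fit`` accepts a list of :class:`EnergyRecord` or a DataFrame/path in the
    energy-table schema; fitted attributes expose the ranking.
    """

    def fit(self, X, y=None):
        if isinstance(X, (str, Path)):
            records = read_energy_table(X)
        elif isinstance(X, pd.DataFrame):
            records = [
                EnergyRecord(
                    monomer_id=str(r.monomer),
                    e_complex=float(r.e_complex),
                    e_template=float(r.e_template),
                    e_monomer=float(r.e_monomer),
                    units=str(getattr(r, "units", "unspecified")),
                )
                for r in X.itertuples(index=False)
            ]
        else:
            records = list(X)
        result = screen_monomers(records)
        self.delta_e_ = result.delta_e
        self.ranking_ = result.ranking
        self.selected_monomer_ = result.selected_monomer
        self.result_ = result
        return self
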