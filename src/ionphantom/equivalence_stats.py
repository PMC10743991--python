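"""Tissue-equivalence comparison statistics.

Per-material means and standard deviations over the beam-energy grid,
signed percent differences against a reference material (soft tissue by
default), per-energy-step increments, per-element recoil shares and
closest-material rankings.  Works identically on simulator output and on
the packaged printed tables.

Two conventions are explicit arguments rather than hidden defaults,
because the source tables mix them: the SD divisor (``population`` = N vs
``sample`` = N-1) and the percent-difference mode (``of_means`` compares
column means; ``mean_of_per_energy`` averages the per-energy percent
differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

REFERENCE_MATERIAL = "ST"

Divisor = Literal["population", "sample"]
PercentMode = Literal["of_means", "mean_of_per_energy"]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyTable:
    """A material x energy matrix of one scalar quantity."""

    quantity: str
    values: pd.DataFrame  # index = energies (MeV/u, ascending), columns = materials

    def __post_init__(self) -> None:
        df = self.values
        if df.isna().any().any():
            raise StatsError(f"{self.quantity}: missing cells")
        energies = df.index.to_numpy(dtype=float)
        if not np.all(np.diff(energies) > 0):
            raise StatsError(f"{self.quantity}: energies must be strictly increasing")
        if len(energies) < 2:
            raise StatsError(f"{self.quantity}: need >= 2 energies")

    @property
    def materials(self) -> list[str]:
        return list(self.values.columns)

    @property
    def energies(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, quantity: str | None = None) -> "EnergyTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(float)
        return cls(quantity or Path(path).stem, df.astype(float))

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="energy_MeV_u")

    def column(self, material: str) -> np.ndarray:
        if material not in self.values.columns:
            raise KeyError(f"unknown material {material!r}")
        return self.values[material].to_numpy(dtype=float)


def column_mean(t: EnergyTable, material: str) -> float:
    """Arithmetic mean of a material's column over the energy grid."""
    return float(t.column(material).mean())


def column_sd(t: EnergyTable, material: str, divisor: Divisor = "population") -> float:
    """Standard deviation of a material's column.

    ``population`` divides by N, ``sample`` by N-1; the source tables use
    both conventions, so the choice is always explicit in reports.
    """
    col = t.column(material)
    if col.size < 2:
        raise StatsError("need at least 2 values for an SD")
    ddof = 0 if divisor == "population" else 1
    return float(col.std(ddof=ddof))


def percent_difference_vs_reference(
        t: EnergyTable, material: str, reference: str = REFERENCE_MATERIAL,
        mode: PercentMode = "of_means") -> float:
    """Signed percent difference of ``material`` from ``reference``.

    Positive when the material's values fall below the reference.
    ``of_means`` -> 100 (mean_ref - mean_mat) / mean_ref;
    ``mean_of_per_energy`` -> energy-wise percent differences, averaged.
    """
    ref = t.column(reference)
    mat = t.column(material)
    if mode == "of_means":
        if ref.mean() == 0:
            raise StatsError("reference mean is zero")
        return float(100.0 * (ref.mean() - mat.mean()) / ref.mean())
    if np.any(ref == 0):
        raise StatsError("reference has a zero entry")
    return float(np.mean(100.0 * (ref - mat) / ref))


def mean_step_increment(t: EnergyTable, material: str,
                        expected_step: float = 20.0) -> float:
    """Mean increase of the quantity per energy step (full precision)."""
    steps = np.diff(t.energies)
    if not np.allclose(steps, expected_step):
        bad = int(np.argmax(~np.isclose(steps, expected_step)))
        raise StatsError(
            f"non-uniform energy spacing at step {bad}: {steps[bad]} MeV/u")
    return float(np.diff(t.column(material)).mean())


@dataclass(frozen=True)
class ComparisonReport:
    """Per-material summary against a reference material."""

    quantity: str
    reference: str
    divisor: Divisor
    percent_mode: PercentMode
    mean: dict[str, float]
    sd: dict[str, float]
    percent_difference: dict[str, float]
    step_increment: dict[str, float]
    ranking: list[str] = field(default_factory=list)
    tied: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.mean, "sd": self.sd,
            "percent_difference_vs_" + self.reference: self.percent_difference,
            "mean_step_increment": self.step_increment,
        })

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "quantity": self.quantity, "reference": self.reference,
            "sd_divisor": self.divisor, "percent_mode": self.percent_mode,
            "mean": self.mean, "sd": self.sd,
            "percent_difference": self.percent_difference,
            "mean_step_increment": self.step_increment,
            "ranking_closest_first": self.ranking, "tied": self.tied,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def closest_material(t: EnergyTable, reference: str = REFERENCE_MATERIAL,
                     mode: PercentMode = "of_means") -> tuple[list[str], bool]:
    """Materials ranked by |percent difference| from the reference,
    closest first; ties broken alphabetically and flagged."""
    others = [m for m in t.materials if m != reference]
    if not others:
        raise StatsError("need at least 2 materials to rank")
    keyed = sorted(
        others,
        key=lambda m: (round(abs(percent_difference_vs_reference(t, m, reference, mode)), 12), m))
    diffs = [round(abs(percent_difference_vs_reference(t, m, reference, mode)), 12)
             for m in keyed]
    tied = len(set(diffs)) < len(diffs)
    return keyed, tied


def compare(t: EnergyTable, reference: str = REFERENCE_MATERIAL,
            divisor: Divisor = "population",
            mode: PercentMode = "of_means") -> ComparisonReport:
    """Full comparison report over every material in the table."""
    ranking, tied = closest_material(t, reference, mode)
    return ComparisonReport(
        quantity=t.quantity, reference=reference, divisor=divisor,
        percent_mode=mode,
        mean={m: column_mean(t, m) for m in t.materials},
        sd={m: column_sd(t, m, divisor) for m in t.materials},
        percent_difference={
            m: percent_difference_vs_reference(t, m, reference, mode)
            for m in t.materials},
        step_increment={m: mean_step_increment(t, m) for m in t.materials},
        ranking=ranking, tied=tied)


def recoil_share_table(shares: pd.DataFrame, tolerance: float = 1.0
                       ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Normalize per-element recoil shares to rows summing to 100 %.

    ``shares``: rows indexed by (material, energy), element columns in
    percent; NaN marks an absent element.  Returns the normalized table,
    the raw row sums, and a list of row labels whose raw sum strays from
    100 by more than ``tolerance`` (printed rows are rounded, so small
    excursions are expected).
    """
    if shares.empty:
        raise StatsError("empty share table")
    raw_sums = shares.sum(axis=1, skipna=True)
    normalized = shares.div(raw_sums, axis=0) * 100.0
    flagged = [str(idx) for idx, s in raw_sums.items()
               if abs(s - 100.0) > tolerance]
    return normalized, raw_sums, flagged
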