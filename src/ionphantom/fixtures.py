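"""Packaged result tables, their self-consistency validator, and a
synthetic table generator.

The packaged CSVs transcribe the published material/result tables cell by
cell, including their printed Average / S.D. summary rows; no cell is ever
silently corrected.  The validator recomputes every summary cell under the
per-table divisor convention (Bragg-peak and collision-event tables:
population; recoil and lateral-straggle tables: sample) and reports each
as pass, fail, or a *known* discrepancy enumerated in
``KNOWN_DISCREPANCIES``.

The synthetic generator produces material x energy tables with a power-law
energy dependence and controllable multiplicative noise, so the analysis
layer can be exercised against planted ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .equivalence_stats import EnergyTable
from .materials import Material, atomic_number_density, packaged_material

ENERGIES = (80.0, 100.0, 120.0, 140.0)

_DATA_FILES = {
    "table1": "table1_number_density.csv",
    "table2": "table2_bragg_peak_mm.csv",
    "table3": "table3_recoils.csv",
    "table4": "table4_collision_events.csv",
    "table5": "table5_lateral_straggle_mm.csv",
}

# sha256 of the packaged CSVs; guards against silent corruption
_CHECKSUMS = {
    "table1_number_density.csv":
        "e59b140445a327f9bb4dc0dfae8703e1cb4ca04202061297c32cefc5979835b6",
    "table2_bragg_peak_mm.csv":
        "c801e7496ccf738420b23e4a16cbdfed219ace5bc29367a5d4a54b051078ba25",
    "table3_recoils.csv":
        "edecede0b00894ccae7426bcbe8bbac119e0c2f9758673e811f65d058107830c",
    "table4_collision_events.csv":
        "715b204236e5c88f48066d178a5bcba970c5bd0977a274cf69e86f32dd152a76",
    "table5_lateral_straggle_mm.csv":
        "fc632159fa008114343d3b870faec1380fcf43dae00bfe1215a924c3e19dbc86",
}

#: printed cells whose recomputation is known not to match; the validator
#: marks these "known" instead of "fail"
KNOWN_DISCREPANCIES = {
    ("table1", "ST", "number_density"):
        "printed 8.88e22/cm^3 vs 8.29e22 from the printed ST composition",
    ("table3", "PMMA", "mean"): "printed mean 2.835 vs recomputed 2.8375",
    ("table3", "Resin", "mean"): "printed mean 3.316 vs recomputed 3.3200",
    ("table3", "row_sums"):
        "printed per-atom percentage rows sum to 99-103, not 100",
    ("prose", "bragg", "Epoxy"):
        "quoted 18.8% below reference; both modes recompute to ~21%",
    ("prose", "straggle", "Water"): "quoted 22.6% vs recomputed 22.7%",
}

#: per-material mean recoil values quoted in the running text (eV/A)
PROSE_RECOIL_MEANS = {"ST": 2.537, "Water": 2.572, "PMMA": 2.835,
                      "Resin": 3.316, "Epoxy": 3.291}


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSet:
    """All packaged tables, parsed, with per-table provenance tags."""

    materials: dict[str, Material]
    table1_number_density: pd.Series  # printed 1e22 atoms/cm^3 column
    table2_bragg: EnergyTable
    table2_printed_summary: pd.DataFrame  # Average / S.D. rows, verbatim
    table3_recoil: pd.DataFrame  # (material, energy) rows: TR + element shares
    table3_printed_sd: pd.DataFrame
    table4: dict[str, EnergyTable]  # vacancies / displacements / replacements
    table4_printed_sd: pd.DataFrame
    table5_straggle: EnergyTable
    table5_printed_summary: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def table3_share_matrix(self) -> pd.DataFrame:
        return self.table3_recoil.drop(columns="TR")


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("ionphantom.data") / name
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(data))


def load_fixtures() -> FixtureSet:
    """Load and checksum-verify the packaged tables."""
    t1 = _read_packaged(_DATA_FILES["table1"]).set_index("material")
    t2 = _read_packaged(_DATA_FILES["table2"]).set_index("row")
    t3 = _read_packaged(_DATA_FILES["table3"])
    t4 = _read_packaged(_DATA_FILES["table4"])
    t5 = _read_packaged(_DATA_FILES["table5"]).set_index("row")

    def split_energy_rows(df: pd.DataFrame, quantity: str):
        body = df.loc[[str(int(e)) for e in ENERGIES]].astype(float)
        body.index = list(ENERGIES)
        summary = df.loc[["Average", "S.D."]].astype(float)
        return EnergyTable(quantity, body), summary

    table2, t2_summary = split_energy_rows(t2.astype(object), "bragg_peak_mm")
    table5, t5_summary = split_energy_rows(t5.astype(object), "lateral_straggle_mm")

    t3 = t3.set_index(["material", "row"])
    t3_body = t3[~t3.index.get_level_values("row").isin(["S.D."])].astype(float)
    t3_body.index = pd.MultiIndex.from_tuples(
        [(m, float(e)) for m, e in t3_body.index], names=["material", "energy"])
    t3_sd = t3.xs("S.D.", level="row").astype(float)

    t4 = t4.set_index(["ce_type", "material"])
    energy_cols = [str(int(e)) for e in ENERGIES]
    table4 = {}
    for ce in ("vacancies", "displacements", "replacements"):
        block = t4.loc[ce, energy_cols].astype(float).T
        block.index = list(ENERGIES)
        table4[ce] = EnergyTable(ce, block)
    t4_sd = t4["S.D."].unstack("ce_type").astype(float)

    mats = {n: packaged_material(n) for n in
            ("ST", "W", "PMMA", "PS", "Resin", "Epoxy")}
    provenance = {k: f"published results table {k[-1]}, transcribed verbatim"
                  for k in _DATA_FILES}
    return FixtureSet(mats, t1["atomic_number_density_1e22"].astype(float),
                      table2, t2_summary, t3_body, t3_sd, table4, t4_sd,
                      table5, t5_summary, provenance)


@dataclass(frozen=True)
class ValidationItem:
    table: str
    cell: str
    printed: float
    recomputed: float
    status: str  # "pass" | "fail" | "known"
    note: str = ""


def _printed_tol(printed: float, decimals: int) -> float:
    return 0.5 * 10.0 ** (-decimals) + 1e-12


def validate_fixtures(f: FixtureSet) -> list[ValidationItem]:
    """Recompute every printed summary cell and compare at printed precision.

    Report-only: returns one :class:`ValidationItem` per cell; expected
    failures listed in ``KNOWN_DISCREPANCIES`` are tagged ``known``.
    """
    items: list[ValidationItem] = []

    def check(table, cell, printed, recomputed, decimals, known_key=None):
        ok = abs(printed - recomputed) <= _printed_tol(printed, decimals)
        status = "pass" if ok else (
            "known" if known_key in KNOWN_DISCREPANCIES else "fail")
        note = KNOWN_DISCREPANCIES.get(known_key, "") if status == "known" else ""
        items.append(ValidationItem(table, cell, printed, recomputed, status, note))

    # table1: derived atomic number density vs printed column
    for name, mat in f.materials.items():
        derived = atomic_number_density(mat)
        printed = float(f.table1_number_density[name])
        ok = abs(derived - printed) / printed <= 0.01
        key = ("table1", name, "number_density")
        status = "pass" if ok else ("known" if key in KNOWN_DISCREPANCIES else "fail")
        items.append(ValidationItem(
            "table1", f"{name} number density", printed, derived, status,
            KNOWN_DISCREPANCIES.get(key, "") if status == "known" else ""))

    # table2 / table5: Average and S.D. rows
    for tid, table, summary, ddof, avg_dec, sd_dec in (
            ("table2", f.table2_bragg, f.table2_printed_summary, 0, 3, 2),
            ("table5", f.table5_straggle, f.table5_printed_summary, 1, 3, 3)):
        for mcol in table.materials:
            col = table.column(mcol)
            check(tid, f"{mcol} Average", float(summary.loc["Average", mcol]),
                  float(col.mean()), avg_dec)
            check(tid, f"{mcol} S.D.", float(summary.loc["S.D.", mcol]),
                  float(col.std(ddof=ddof)), sd_dec)

    # table4: printed S.D. column (population), integer precision
    for ce, table in f.table4.items():
        for mcol in table.materials:
            check("table4", f"{ce} {mcol} S.D.",
                  float(f.table4_printed_sd.loc[mcol, ce]),
                  float(table.column(mcol).std(ddof=0)), 0)

    # table3: per-material recoil means vs prose values; S.D. rows (sample)
    for mat, grp in f.table3_recoil.groupby(level="material", sort=False):
        tr = grp["TR"].to_numpy(dtype=float)
        if mat in PROSE_RECOIL_MEANS:
            check("table3", f"{mat} T.R. mean", PROSE_RECOIL_MEANS[mat],
                  float(tr.mean()), 3, known_key=("table3", mat, "mean"))
        printed_sd = float(f.table3_printed_sd.loc[mat, "TR"])
        dec = 3 if mat == "Epoxy" else 2
        check("table3", f"{mat} T.R. S.D.", printed_sd,
              float(tr.std(ddof=1)), dec)

    # table3: share rows should sum to ~100
    sums = f.table3_share_matrix.sum(axis=1, skipna=True)
    for (mat, energy), s in sums.items():
        key = ("table3", "row_sums")
        if abs(s - 100.0) <= 0.3:
            items.append(ValidationItem(
                "table3", f"{mat} {energy:g} share sum", 100.0, float(s), "pass"))
        else:
            items.append(ValidationItem(
                "table3", f"{mat} {energy:g} share sum", 100.0, float(s),
                "known", KNOWN_DISCREPANCIES[key]))
    return items


def validation_summary(items: list[ValidationItem]) -> dict[str, int]:
    out = {"pass": 0, "fail": 0, "known": 0}
    for it in items:
        out[it.status] += 1
    return out


# -- synthetic tables ------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic material x energy table.

    Values follow ``scale_m * E^exponent * (1 + eps)`` with
    ``eps ~ Normal(0, noise)``; exponent 1.7 mimics the range-energy power
    law of light ions in the therapeutic window.
    """

    material_scales: dict[str, float]
    energies: tuple[float, ...] = ENERGIES
    exponent: float = 1.7
    noise: float = 0.0
    seed: int = 0
    quantity: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if any(s <= 0 for s in self.material_scales.values()):
            raise ValueError("material scales must be positive")


def generate_synthetic_table(s: SyntheticSpec) -> EnergyTable:
    """Draw a reproducible synthetic :class:`EnergyTable` from ``s``."""
    rng = np.random.default_rng(s.seed)
    energies = np.asarray(s.energies, dtype=float)
    base = energies[:, None] ** s.exponent
    scales = np.array(list(s.material_scales.values()))[None, :]
    eps = rng.normal(0.0, s.noise, size=(energies.size, scales.size)) if s.noise else 0.0
    values = scales * base * (1.0 + eps)
    df = pd.DataFrame(values, index=energies, columns=list(s.material_scales))
    return EnergyTable(s.quantity, df)


def export_fixtures(out_dir: str | Path) -> list[Path]:
    """Dump the packaged CSVs into ``out_dir``; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _DATA_FILES.values():
        data = (resources.files("ionphantom.data") / name).read_bytes()
        target = out / name
        target.write_bytes(data)
        written.append(target)
    return written
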