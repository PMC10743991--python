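"""Phantom material data model.

A :class:`Material` couples a mass density with an elemental composition
(both atomic and mass fractions, one derived from the other) plus the
per-element lattice energies (displacement, binding, surface) that the
damage model consumes.  Six tissue-equivalent phantom definitions ship with
the package: soft tissue (``ST``), liquid water (``W``), ``PMMA``, ``PS``
(polystyrene), ``Resin`` and ``Epoxy``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

AVOGADRO = 6.02214076e23  # 1/mol

PACKAGED_MATERIALS = ("ST", "W", "PMMA", "PS", "Resin", "Epoxy")


class MaterialError(ValueError):
    """Raised for malformed material definitions."""


def _element_registry() -> pd.DataFrame:
    with resources.as_file(resources.files("ionphantom.data") / "elements.csv") as p:
        df = pd.read_csv(p)
    return df.set_index("symbol")


_ELEMENTS = _element_registry()


@dataclass(frozen=True)
class ElementSpec:
    """One constituent element with its lattice energies.

    ``Ed``/``Eb``/``Es`` are the threshold displacement, lattice binding and
    surface binding energies (eV).  ``I_elem`` is the elemental mean
    excitation energy (eV) entering Bragg additivity.
    """

    symbol: str
    Z: int
    atomic_mass: float  # u
    I_elem: float  # eV
    Ed: float  # eV
    Eb: float = 3.0  # eV
    Es: float = 2.0  # eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise MaterialError(f"{self.symbol}: Z must be >= 1")
        if self.atomic_mass <= 0 or self.I_elem <= 0:
            raise MaterialError(f"{self.symbol}: atomic mass and I must be positive")
        if not (self.Ed >= self.Eb >= 0) or self.Es < 0:
            raise MaterialError(f"{self.symbol}: need Ed >= Eb >= 0 and Es >= 0")

    @classmethod
    def from_symbol(cls, symbol: str, Ed: float, Eb: float = 3.0, Es: float = 2.0) -> "ElementSpec":
        if symbol not in _ELEMENTS.index:
            raise MaterialError(f"unknown element symbol {symbol!r}")
        row = _ELEMENTS.loc[symbol]
        return cls(symbol, int(row["Z"]), float(row["atomic_mass_u"]),
                   float(row["I_eV"]), Ed, Eb, Es)


@dataclass(frozen=True)
class Component:
    element: ElementSpec
    atomic_fraction: float
    mass_fraction: float


@dataclass(frozen=True)
class Material:
    """A homogeneous compound target."""

    name: str
    mass_density: float  # g/cm^3
    components: tuple[Component, ...]
    I_override: float | None = None  # compound mean excitation energy, eV

    def __post_init__(self) -> None:
        if self.mass_density < 0:
            raise MaterialError(f"{self.name}: density must be non-negative")
        if not self.components:
            raise MaterialError(f"{self.name}: empty composition")
        fa = sum(c.atomic_fraction for c in self.components)
        fw = sum(c.mass_fraction for c in self.components)
        if abs(fa - 1) > 0.02 or abs(fw - 1) > 0.02:
            raise MaterialError(
                f"{self.name}: fractions must sum to 1 +- 0.02 (atomic {fa:.4f}, mass {fw:.4f})")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_atomic_fractions(cls, name: str, mass_density: float,
                              elements: list[tuple[ElementSpec, float]],
                              I_override: float | None = None) -> "Material":
        total = sum(f for _, f in elements)
        _check_prenormalized(name, total)
        mean_a = sum(f * e.atomic_mass for e, f in elements) / total
        comps = tuple(
            Component(e, f / total, (f / total) * e.atomic_mass / mean_a)
            for e, f in elements)
        return cls(name, mass_density, comps, I_override)

    @classmethod
    def from_mass_fractions(cls, name: str, mass_density: float,
                            elements: list[tuple[ElementSpec, float]],
                            I_override: float | None = None) -> "Material":
        total = sum(w for _, w in elements)
        _check_prenormalized(name, total)
        inv_mean_a = sum((w / total) / e.atomic_mass for e, w in elements)
        comps = tuple(
            Component(e, (w / total) / e.atomic_mass / inv_mean_a, w / total)
            for e, w in elements)
        return cls(name, mass_density, comps, I_override)

    def with_density(self, mass_density: float) -> "Material":
        return replace(self, mass_density=mass_density)

    # -- derived quantities ------------------------------------------------

    @property
    def mean_atomic_mass(self) -> float:
        """Atomic-fraction-weighted mean atomic mass <A>, u."""
        return sum(c.atomic_fraction * c.element.atomic_mass for c in self.components)

    @property
    def mean_z_over_a(self) -> float:
        """Mass-fraction-weighted <Z/A> (electrons per u)."""
        return sum(c.mass_fraction * c.element.Z / c.element.atomic_mass
                   for c in self.components)

    @property
    def atoms_per_formula_volume(self) -> float:
        """Atomic number density in units of 1e22 atoms/cm^3."""
        return atomic_number_density(self)

    def element(self, symbol: str) -> Component:
        for c in self.components:
            if c.element.symbol == symbol:
                return c
        raise KeyError(symbol)


@dataclass(frozen=True)
class Phantom:
    """Beam-facing slab geometry: depth along the beam, square lateral face."""

    material: Material
    depth: float = 150.0  # mm
    lateral_extent: float = 80.0  # mm

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.lateral_extent <= 0:
            raise MaterialError("phantom dimensions must be positive")


def _check_prenormalized(name: str, total: float) -> None:
    # printed compositions are rounded percentages; reject only gross errors
    if not (0.9 <= total <= 1.1):
        raise MaterialError(
            f"{name}: fractions sum to {total:.4f}, outside [0.9, 1.1] before normalization")


def atomic_number_density(m: Material) -> float:
    """Atomic number density rho*N_A/<A>, in 1e22 atoms/cm^3."""
    if m.mass_density < 0:
        raise MaterialError("density must be non-negative")
    return m.mass_density * AVOGADRO / m.mean_atomic_mass / 1e22


def mean_excitation_energy(m: Material) -> float:
    """Compound mean excitation energy I (eV).

    Bragg additivity in the logarithm,
    ``ln I = sum_i w_i (Z_i/A_i) ln I_i / sum_i w_i (Z_i/A_i)``,
    unless the material carries a tabulated compound value (water: 75 eV),
    which takes precedence.
    """
    if m.I_override is not None:
        return m.I_override
    num = den = 0.0
    for c in m.components:
        weight = c.mass_fraction * c.element.Z / c.element.atomic_mass
        num += weight * math.log(c.element.I_elem)
        den += weight
    return math.exp(num / den)


# -- file formats ----------------------------------------------------------

def load_material(path: str | Path) -> Material:
    """Load a flat key-value material definition file.

    Lines: ``name <str>``, ``density_g_cm3 <float>``, optional ``I_eV <float>``
    and one ``element <symbol> atomic_percent=... | mass_percent=...
    Ed_eV=... Eb_eV=... Es_eV=...`` line per constituent.  Whichever fraction
    set is given, the other is derived; both are normalized to sum to 1.
    """
    path = Path(path)
    name = None
    density = None
    i_override = None
    atomic: list[tuple[ElementSpec, float]] = []
    mass: list[tuple[ElementSpec, float]] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, *rest = line.split()
        if key == "name":
            name = rest[0]
        elif key == "density_g_cm3":
            density = float(rest[0])
        elif key == "I_eV":
            i_override = float(rest[0])
        elif key == "element":
            symbol = rest[0]
            kv = dict(item.split("=", 1) for item in rest[1:])
            spec = ElementSpec.from_symbol(
                symbol, Ed=float(kv["Ed_eV"]),
                Eb=float(kv.get("Eb_eV", 3.0)), Es=float(kv.get("Es_eV", 2.0)))
            if "atomic_percent" in kv:
                atomic.append((spec, float(kv["atomic_percent"]) / 100.0))
            elif "mass_percent" in kv:
                mass.append((spec, float(kv["mass_percent"]) / 100.0))
            else:
                raise MaterialError(f"{path}: element {symbol} lacks a fraction")
        else:
            raise MaterialError(f"{path}: unknown key {key!r}")
    if name is None or density is None:
        raise MaterialError(f"{path}: missing name or density")
    if atomic and mass:
        raise MaterialError(f"{name}: mix of atomic_percent and mass_percent entries")
    if atomic:
        return Material.from_atomic_fractions(name, density, atomic, i_override)
    if mass:
        return Material.from_mass_fractions(name, density, mass, i_override)
    raise MaterialError(f"{name}: no elements declared")


def load_materials_csv(path: str | Path) -> dict[str, Material]:
    """Load materials from a CSV with one row per (material, element).

    Columns: material, density_g_cm3, symbol, atomic_percent and/or
    mass_percent, Ed_eV, Eb_eV, Es_eV, optional I_eV (per material).
    """
    df = pd.read_csv(path)
    out: dict[str, Material] = {}
    for name, grp in df.groupby("material", sort=False):
        density = float(grp["density_g_cm3"].iloc[0])
        i_override = None
        if "I_eV" in grp.columns and pd.notna(grp["I_eV"].iloc[0]):
            i_override = float(grp["I_eV"].iloc[0])
        elements = []
        use_atomic = "atomic_percent" in grp.columns and grp["atomic_percent"].notna().all()
        for _, row in grp.iterrows():
            spec = ElementSpec.from_symbol(
                str(row["symbol"]), Ed=float(row["Ed_eV"]),
                Eb=float(row.get("Eb_eV", 3.0)), Es=float(row.get("Es_eV", 2.0)))
            frac = float(row["atomic_percent"] if use_atomic else row["mass_percent"]) / 100.0
            elements.append((spec, frac))
        ctor = Material.from_atomic_fractions if use_atomic else Material.from_mass_fractions
        out[str(name)] = ctor(str(name), density, elements, i_override)
    return out


def packaged_material(name: str) -> Material:
    """Return one of the packaged phantom materials by name."""
    ref = resources.files("ionphantom.data") / "materials" / f"{name}.mat"
    if not ref.is_file():
        raise KeyError(f"no packaged material named {name!r}")
    with resources.as_file(ref) as p:
        return load_material(p)
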