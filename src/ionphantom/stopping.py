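"""Stopping powers, CSDA ranges and range straggling for light ions.

Electronic stopping is the Bethe formula with a Barkas-type effective
charge; nuclear stopping is the ZBL universal reduced-energy fit.  Both are
evaluated per element and mixed by Bragg additivity (mass-fraction weights),
with the compound mean excitation energy from
:func:`ionphantom.materials.mean_excitation_energy`.

Unit conventions: beam energies in MeV/u, mass stopping in MeV cm^2/g,
linear quantities in mm; LET in eV/Angstrom (1 MeV/mm = 0.1 eV/A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .materials import AVOGADRO, Material

# physical constants
ELECTRON_MASS_MEV = 0.51099895
ATOMIC_MASS_MEV = 931.49410  # energy equivalent of 1 u
K_BETHE = 0.307075  # 4 pi N_A r_e^2 m_e c^2, MeV cm^2/mol
OMEGA0 = K_BETHE * ELECTRON_MASS_MEV  # Bohr straggling constant, MeV^2 cm^2/g per (Z/A)

E_FLOOR = 0.1  # MeV/u; below this the Bethe formula is replaced by a
               # velocity-proportional extrapolation matched at the floor

MEV_PER_MM_TO_EV_PER_A = 0.1


class StoppingError(ValueError):
    pass


@dataclass(frozen=True)
class BeamSpec:
    """Primary beam: a bare ion at a kinetic energy per nucleon."""

    energy_per_nucleon: float  # MeV/u
    ion_Z: int = 3
    ion_A: float = 7.0
    n_particles: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.energy_per_nucleon <= 0:
            raise StoppingError("energy_per_nucleon must be positive")
        if self.n_particles < 1:
            raise StoppingError("n_particles must be >= 1")


@dataclass(frozen=True)
class StoppingResult:
    electronic: float  # MeV cm^2/g
    nuclear: float  # MeV cm^2/g
    linear_total: float  # eV/Angstrom

    @property
    def total(self) -> float:
        return self.electronic + self.nuclear


def beta_gamma(energy_per_nucleon):
    """(beta^2, gamma) for a given kinetic energy per nucleon."""
    gamma = 1.0 + np.asarray(energy_per_nucleon, dtype=float) / ATOMIC_MASS_MEV
    beta2 = 1.0 - 1.0 / gamma**2
    return beta2, gamma


def effective_charge(ion_Z: int, beta):
    """Barkas effective charge z*(beta) = z (1 - exp(-125 beta z^(-2/3)))."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise StoppingError("beta must lie in (0, 1)")
    z = float(ion_Z)
    return z * (1.0 - np.exp(-125.0 * beta * z ** (-2.0 / 3.0)))


def _bethe_mass_stopping(E, m: Material, ion_Z: int, I_eV: float):
    """Bethe electronic mass stopping, MeV cm^2/g, valid above ``E_FLOOR``."""
    beta2, gamma = beta_gamma(E)
    zeff = effective_charge(ion_Z, np.sqrt(beta2))
    i_mev = I_eV * 1e-6
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma**2 / i_mev
    bracket = np.log(arg) - beta2
    return K_BETHE * zeff**2 * m.mean_z_over_a / beta2 * bracket


def electronic_stopping(E, m: Material, ion_Z: int = 3,
                        extrapolate: bool = True):
    """Electronic mass stopping power at energy ``E`` (MeV/u), MeV cm^2/g.

    Below the 0.1 MeV/u validity floor a velocity-proportional
    (S proportional to sqrt(E)) extrapolation matched at the floor is used;
    pass ``extrapolate=False`` to make that a domain error instead.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise StoppingError("energy must be positive")
    I_eV = _material_I(m)
    low = E < E_FLOOR
    if np.any(low) and not extrapolate:
        raise StoppingError(f"energy below validity floor {E_FLOOR} MeV/u")
    out = np.empty_like(E)
    if np.any(~low):
        out[~low] = _bethe_mass_stopping(E[~low], m, ion_Z, I_eV)
    if np.any(low):
        s_floor = _bethe_mass_stopping(np.array(E_FLOOR), m, ion_Z, I_eV)
        out[low] = s_floor * np.sqrt(E[low] / E_FLOOR)
    return out if out.ndim else float(out)


def zbl_reduced_stopping(eps):
    """ZBL universal reduced nuclear stopping s_n(eps)."""
    eps = np.asarray(eps, dtype=float)
    small = eps <= 30.0
    out = np.empty_like(eps)
    e = eps[small]
    out[small] = np.log1p(1.1383 * e) / (
        2.0 * (e + 0.01321 * e**0.21226 + 0.19593 * np.sqrt(e)))
    e = eps[~small]
    out[~small] = np.log(e) / (2.0 * e)
    return out if out.ndim else float(out)


def _zbl_element(E, z1: int, a1: float, z2: int, a2: float):
    """ZBL nuclear stopping cross-section per target atom, eV cm^2/atom."""
    e_kev = np.asarray(E, dtype=float) * a1 * 1000.0  # total kinetic energy
    screen = z1**0.23 + z2**0.23
    eps = 32.53 * a2 * e_kev / (z1 * z2 * (a1 + a2) * screen)
    sn = zbl_reduced_stopping(eps)
    return 8.462e-15 * z1 * z2 * a1 * sn / ((a1 + a2) * screen)


def nuclear_stopping(E, m: Material, ion_Z: int = 3, ion_A: float = 7.0):
    """ZBL nuclear mass stopping power at ``E`` (MeV/u), MeV cm^2/g."""
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise StoppingError("energy must be positive")
    total = 0.0
    for c in m.components:
        per_atom = _zbl_element(E, ion_Z, ion_A, c.element.Z, c.element.atomic_mass)
        total = total + c.mass_fraction * per_atom * AVOGADRO / c.element.atomic_mass
    total = total * 1e-6  # eV -> MeV
    return total if np.ndim(total) else float(total)


def nuclear_stopping_per_element(E, m: Material, ion_Z: int = 3, ion_A: float = 7.0):
    """Per-element contributions f_i * sigma_i(E) to the nuclear stopping.

    Returns (symbols, array of shape (n_elements,) + shape(E)) in
    MeV cm^2/g units, summing to :func:`nuclear_stopping`.
    """
    symbols = [c.element.symbol for c in m.components]
    parts = [
        c.mass_fraction * _zbl_element(E, ion_Z, ion_A, c.element.Z,
                                       c.element.atomic_mass)
        * AVOGADRO / c.element.atomic_mass * 1e-6
        for c in m.components
    ]
    return symbols, np.asarray(parts)


def total_mass_stopping(E, m: Material, ion_Z: int = 3, ion_A: float = 7.0):
    return electronic_stopping(E, m, ion_Z) + nuclear_stopping(E, m, ion_Z, ion_A)


def stopping_at(E: float, m: Material, ion_Z: int = 3, ion_A: float = 7.0) -> StoppingResult:
    """Full stopping breakdown at one energy, with the linear LET in eV/A."""
    se = float(electronic_stopping(E, m, ion_Z))
    sn = float(nuclear_stopping(E, m, ion_Z, ion_A))
    linear = (se + sn) * m.mass_density * 0.1 * MEV_PER_MM_TO_EV_PER_A
    return StoppingResult(se, sn, linear)


def bohr_straggling_mass(E, m: Material, ion_Z: int = 3):
    """Bohr energy-loss straggling d(Omega^2)/d(rho x), MeV^2 cm^2/g.

    Includes the relativistic Fano factor (1 - beta^2/2)/(1 - beta^2).
    """
    beta2, _ = beta_gamma(E)
    zeff = effective_charge(ion_Z, np.sqrt(beta2))
    rel = (1.0 - beta2 / 2.0) / (1.0 - beta2)
    return OMEGA0 * zeff**2 * m.mean_z_over_a * rel


class RangeEnergyTable:
    """Precomputed range-energy relation for one (ion, material) pair.

    Integrates dE/S_total on a log-spaced grid from ``E_FLOOR`` to ``e_max``
    (trapezoid in ln E, >= ``n_nodes`` nodes) and adds the closed-form
    residual range of the velocity-proportional sub-floor extrapolation
    (2 * E_FLOOR / S(E_FLOOR)).  Provides both R(E) and E(R) interpolants.
    """

    def __init__(self, m: Material, ion_Z: int = 3, ion_A: float = 7.0,
                 e_max: float = 200.0, n_nodes: int = 1024):
        if m.mass_density <= 0:
            raise StoppingError("material density must be positive for ranges")
        self.material = m
        self.ion_Z = ion_Z
        self.ion_A = ion_A
        grid = np.geomspace(E_FLOOR, e_max, n_nodes)
        s_tot = total_mass_stopping(grid, m, ion_Z, ion_A)  # MeV cm^2/g per u... see below
        # dR = A dE_u / S with S the total-energy stopping; S here is per ion
        # total energy, E in MeV/u, so scale by ion_A
        integrand = ion_A / s_tot  # g/cm^2 per (MeV/u)
        # cumulative trapezoid in ln E: dE = E d(lnE)
        lng = np.log(grid)
        vals = integrand * grid
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(lng))])
        residual = 2.0 * E_FLOOR * ion_A / float(s_tot[0])
        mass_range = cum + residual  # g/cm^2
        self._e_grid = grid
        self._s_tot = s_tot
        self.residual_range_mm = residual / m.mass_density * 10.0
        self._range_mm = mass_range / m.mass_density * 10.0
        self._r_of_e = PchipInterpolator(grid, self._range_mm, extrapolate=False)
        self._e_of_r = PchipInterpolator(self._range_mm, grid, extrapolate=False)

    def range_mm(self, E):
        """CSDA range (mm) at energy E (MeV/u)."""
        E = np.asarray(E, dtype=float)
        out = np.where(E <= E_FLOOR,
                       self.residual_range_mm * (E / E_FLOOR) ** 1.5,
                       self._r_of_e(np.clip(E, E_FLOOR, None)))
        return out if out.ndim else float(out)

    def energy_at_range(self, r_mm):
        """Inverse relation: residual energy (MeV/u) at residual range r_mm."""
        r = np.asarray(r_mm, dtype=float)
        rres = self.residual_range_mm
        out = np.where(
            r <= rres,
            E_FLOOR * np.clip(r / rres, 0.0, 1.0) ** (2.0 / 3.0),
            self._e_of_r(np.clip(r, rres, self._range_mm[-1])))
        return out if out.ndim else float(out)

    def linear_stopping(self, E):
        """Total linear stopping (MeV/mm) at E (MeV/u)."""
        s = total_mass_stopping(np.clip(E, 1e-6, None), self.material,
                                self.ion_Z, self.ion_A)
        return s * self.material.mass_density * 0.1


_TABLE_CACHE: dict[tuple, RangeEnergyTable] = {}


def range_energy_table(m: Material, ion_Z: int = 3, ion_A: float = 7.0) -> RangeEnergyTable:
    """Memoized :class:`RangeEnergyTable` (materials are frozen dataclasses)."""
    key = (m, ion_Z, ion_A)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = RangeEnergyTable(m, ion_Z, ion_A)
    return _TABLE_CACHE[key]


def csda_range(E0: float, m: Material, ion_Z: int = 3, ion_A: float = 7.0) -> float:
    """CSDA range (mm) of the ion entering at ``E0`` MeV/u."""
    if not (E_FLOOR < E0 <= 1000.0):
        raise StoppingError("E0 must lie in (0.1, 1000] MeV/u")
    return float(range_energy_table(m, ion_Z, ion_A).range_mm(E0))


def range_straggle_sigma(E0: float, m: Material, ion_Z: int = 3,
                         ion_A: float = 7.0) -> float:
    """Longitudinal range-straggling sigma_R (mm), Bohr variance propagated.

    sigma_R^2 = integral_0^E0 omega(E) / S_lin(E)^3 dE with omega the linear
    Bohr straggling power and S_lin the linear total stopping (per-ion total
    energy scale).
    """
    if E0 <= E_FLOOR:
        raise StoppingError("E0 must exceed the 0.1 MeV/u floor")
    m_rho = m.mass_density
    grid = np.geomspace(E_FLOOR, E0, 768)
    s_lin = total_mass_stopping(grid, m, ion_Z, ion_A) * m_rho * 0.1  # MeV/mm
    omega_lin = bohr_straggling_mass(grid, m, ion_Z) * m_rho * 0.1  # MeV^2/mm
    # energies are per nucleon: dE_total = ion_A * dE_u
    integrand = omega_lin / s_lin**3 * ion_A
    lng = np.log(grid)
    vals = integrand * grid
    var = float(np.sum(0.5 * (vals[1:] + vals[:-1]) * np.diff(lng)))
    return math.sqrt(var)


def _material_I(m: Material) -> float:
    from .materials import mean_excitation_energy

    return mean_excitation_energy(m)
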