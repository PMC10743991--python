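"""Depth-LET Bragg curves and condensed-history Monte Carlo transport.

The deterministic Bragg curve inverts the range-energy relation to get the
residual energy at each depth, evaluates the linear stopping there, and
convolves with a Gaussian of the Bohr range-straggling width.  The Monte
Carlo tracks ions in lockstep on a fixed relative-energy-loss grid
(dE/E = 2 % per step), sampling per-step path-length straggling (Bohr
variance) and Highland multiple-scattering deflections, and records the
3-D endpoint of every track.

Coordinates: beam along +x, entry face at x = 0, transverse plane (y, z).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .materials import Material, Phantom
from .stopping import (
    ATOMIC_MASS_MEV,
    E_FLOOR,
    BeamSpec,
    beta_gamma,
    bohr_straggling_mass,
    csda_range,
    range_energy_table,
    range_straggle_sigma,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = 0.1  # mm
RELATIVE_ENERGY_STEP = 0.02  # dE/E per condensed-history step


class TransportError(ValueError):
    pass


@dataclass(frozen=True)
class DepthProfile:
    """LET-vs-depth curve for one (beam, material) pair."""

    depth_mm: np.ndarray  # uniform grid over [0, phantom depth]
    let_eV_per_A: np.ndarray
    E0: float  # MeV/u
    material_name: str

    def __post_init__(self) -> None:
        if self.depth_mm.shape != self.let_eV_per_A.shape:
            raise TransportError("depth and LET grids differ in length")
        if np.any(self.let_eV_per_A < 0):
            raise TransportError("LET values must be non-negative")


@dataclass(frozen=True)
class TrackEndpointSet:
    """Final coordinates of every simulated ion track."""

    x: np.ndarray  # projected depth, mm
    y: np.ndarray  # transverse, mm
    z: np.ndarray  # transverse, mm
    seed: int
    material_name: str
    E0: float

    @property
    def N(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class StraggleResult:
    R_p: float  # mean projected range, mm
    sigma_long: float  # mm
    sigma_lat: float  # mm


def bragg_curve(b: BeamSpec, p: Phantom, grid_step: float = DEFAULT_GRID_STEP,
                sigma_override: float | None = None) -> DepthProfile:
    """Deterministic depth-LET profile with Gaussian range-straggling blur.

    ``sigma_override`` replaces the Bohr range-straggling width (mm); pass
    0.0 for an unblurred curve whose peak sits at the CSDA range.
    """
    if not (0.01 < grid_step <= 1.0):
        raise TransportError("grid_step must lie in (0.01, 1] mm")
    m = p.material
    table = range_energy_table(m, b.ion_Z, b.ion_A)
    r0 = float(table.range_mm(b.energy_per_nucleon))
    if r0 > p.depth:
        logger.warning(
            "phantom depth %.1f mm truncates the %.1f mm range; profile clipped",
            p.depth, r0)
    depth = np.arange(0.0, p.depth + 0.5 * grid_step, grid_step)
    residual = r0 - depth
    e_res = np.where(residual > 0, table.energy_at_range(np.clip(residual, 0, None)), 0.0)
    let = np.where(e_res > 0, table.linear_stopping(np.clip(e_res, 1e-6, None)) * 0.1, 0.0)

    sigma = (range_straggle_sigma(b.energy_per_nucleon, m, b.ion_Z, b.ion_A)
             if sigma_override is None else float(sigma_override))
    if sigma > 0:
        half = int(math.ceil(4.0 * sigma / grid_step))
        kx = np.arange(-half, half + 1) * grid_step
        kernel = np.exp(-0.5 * (kx / sigma) ** 2)
        kernel /= kernel.sum()
        let = np.convolve(let, kernel, mode="same")
    # straggling cannot push dose beyond range + 4 sigma
    let[depth > r0 + 4.0 * sigma] = 0.0
    return DepthProfile(depth, let, b.energy_per_nucleon, m.name)


def bragg_peak_position(dp: DepthProfile) -> float:
    """Peak depth (mm), argmax refined by 3-point parabolic interpolation."""
    let = dp.let_eV_per_A
    if let.size == 0:
        raise TransportError("empty profile")
    if np.allclose(let, let[0]):
        raise TransportError("no peak: profile is flat")
    k = int(np.argmax(let))
    if 0 < k < let.size - 1:
        y0, y1, y2 = let[k - 1], let[k], let[k + 1]
        if y2 == 0.0:
            # range-end cusp (unblurred curve): a parabola through the
            # zero cell would drag the vertex backwards
            return float(dp.depth_mm[k])
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            return float(dp.depth_mm[k] + shift * (dp.depth_mm[1] - dp.depth_mm[0]))
    return float(dp.depth_mm[k])


def _radiation_length_mm(m: Material) -> float:
    """Composite radiation length from Tsai's per-element approximation."""
    inv = 0.0
    for c in m.components:
        z, a = c.element.Z, c.element.atomic_mass
        x0 = 716.4 * a / (z * (z + 1) * math.log(287.0 / math.sqrt(z)))  # g/cm^2
        inv += c.mass_fraction / x0
    return (1.0 / inv) / m.mass_density * 10.0  # mm


def simulate_tracks(b: BeamSpec, p: Phantom, *, scattering: bool = True,
                    straggling: bool = True) -> TrackEndpointSet:
    """Condensed-history Monte Carlo of ``b.n_particles`` ion tracks.

    All tracks march down a shared energy grid with 2 % relative energy loss
    per step; each step samples a path length (mean dE/S, Bohr-straggling
    spread) and a Highland scattering deflection.  With both effects off,
    every endpoint collapses onto the CSDA range on the beam axis.
    """
    m = p.material
    table = range_energy_table(m, b.ion_Z, b.ion_A)
    rng = np.random.default_rng(b.seed)
    n = b.n_particles

    # shared energy grid
    e_grid = [b.energy_per_nucleon]
    while e_grid[-1] > E_FLOOR:
        e_grid.append(max(e_grid[-1] * (1.0 - RELATIVE_ENERGY_STEP), E_FLOOR))
    e_grid = np.asarray(e_grid)
    e_mid = np.sqrt(e_grid[:-1] * e_grid[1:])
    de_total = (e_grid[:-1] - e_grid[1:]) * b.ion_A  # MeV per step

    s_lin = table.linear_stopping(e_mid)  # MeV/mm
    ds_mean = de_total / s_lin  # mm
    omega_lin = bohr_straggling_mass(e_mid, m, b.ion_Z) * m.mass_density * 0.1
    sigma_s = np.sqrt(omega_lin * ds_mean) / s_lin  # mm, per-step path spread

    beta2, _ = beta_gamma(e_mid)
    pc_per_u = np.sqrt(e_mid * (e_mid + 2.0 * ATOMIC_MASS_MEV))  # MeV per u
    pbeta = pc_per_u * np.sqrt(beta2) * b.ion_A  # p*beta*c, MeV
    x0_mm = _radiation_length_mm(m)
    t_ratio = ds_mean / x0_mm
    log_corr = 1.0 + 0.038 * np.log(np.clip(t_ratio * b.ion_Z**2 / beta2, 1e-12, None))
    theta0 = 13.6 / pbeta * b.ion_Z * np.sqrt(t_ratio) * np.clip(log_corr, 0.25, None)

    x = np.zeros(n)
    y = np.zeros(n)
    z = np.zeros(n)
    ty = np.zeros(n)  # small-angle direction tangents
    tz = np.zeros(n)
    for k in range(e_mid.size):
        if straggling:
            ds = np.clip(ds_mean[k] + sigma_s[k] * rng.standard_normal(n), 0.0, None)
        else:
            ds = ds_mean[k]
        if scattering:
            dty = theta0[k] * rng.standard_normal(n)
            dtz = theta0[k] * rng.standard_normal(n)
        else:
            dty = dtz = 0.0
        # detour: depth advance shortened by the transverse slope
        slope2 = ty**2 + tz**2
        x += ds * (1.0 - 0.5 * slope2)
        y += ds * (ty + 0.5 * dty)
        z += ds * (tz + 0.5 * dtz)
        ty = ty + dty
        tz = tz + dtz
    # residual sub-floor straight-ahead range
    ds = table.residual_range_mm
    x += ds * (1.0 - 0.5 * (ty**2 + tz**2))
    y += ds * ty
    z += ds * tz
    return TrackEndpointSet(x, y, z, b.seed, m.name, b.energy_per_nucleon)


def longitudinal_straggle(t: TrackEndpointSet) -> StraggleResult:
    """Population statistics of the projected range distribution.

    R_p = sum(x_i)/N and sigma = sqrt(sum(x_i^2)/N - R_p^2) - divisor N.
    """
    x = np.asarray(t.x, dtype=float)
    rp = float(x.sum() / x.size)
    var = float((x**2).sum() / x.size - rp**2)
    sigma_long = math.sqrt(max(var, 0.0))
    return StraggleResult(rp, sigma_long, lateral_straggle(t))


def lateral_straggle(t: TrackEndpointSet) -> float:
    """sigma_y = sqrt( sum_i ((|y_i|+|z_i|)/2)^2 / N )."""
    r = (np.abs(t.y) + np.abs(t.z)) / 2.0
    return float(math.sqrt(float((r**2).mean())))


def straggle_statistics(t: TrackEndpointSet) -> StraggleResult:
    return longitudinal_straggle(t)


def simulate_straggle(material: Material, energy: float, n_particles: int = 100_000,
                      seed: int = 0, depth_mm: float = 150.0) -> StraggleResult:
    """Convenience wrapper: run the MC and reduce to straggle statistics."""
    beam = BeamSpec(energy, n_particles=n_particles, seed=seed)
    endpoints = simulate_tracks(beam, Phantom(material, depth=depth_mm))
    return longitudinal_straggle(endpoints)
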