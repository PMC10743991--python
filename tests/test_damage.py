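"""Displacement-damage model: Kinchin-Pease, Lindhard partition, cascades."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionphantom.damage import (
    DamageError,
    DamageModelParams,
    damage_energy,
    energy_partition,
    kinchin_pease_displacements,
    nrt_scale,
    recoil_partition,
)
from ionphantom.materials import AVOGADRO, ElementSpec, Material
from ionphantom.stopping import BeamSpec


class TestKinchinPease:
    @pytest.mark.parametrize("ev_factor,expected", [
        (0.5, 0.0),   # below threshold
        (2.0, 1.0),   # single-displacement plateau
        (10.0, 4.0),  # 0.8 * 10 Ed / (2 Ed)
    ])
    def test_branch_values(self, ev_factor, expected):
        ed = 28.0
        assert kinchin_pease_displacements(ev_factor * ed, ed) == expected

    def test_continuous_at_plateau_edge(self):
        ed = 28.0
        assert kinchin_pease_displacements(2.5 * ed, ed) == pytest.approx(1.0)
        assert kinchin_pease_displacements(2.5 * ed - 1e-9, ed) == 1.0

    @given(st.floats(1.0, 1e6), st.floats(1.0, 1e6), st.floats(5.0, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_damage_energy(self, ev1, ev2, ed):
        lo, hi = sorted((ev1, ev2))
        assert (kinchin_pease_displacements(lo, ed)
                <= kinchin_pease_displacements(hi, ed))

    @given(st.floats(1.0, 1e5), st.floats(5.0, 100.0), st.floats(5.0, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_non_increasing_in_threshold(self, ev, ed1, ed2):
        lo, hi = sorted((ed1, ed2))
        assert (kinchin_pease_displacements(ev, hi)
                <= kinchin_pease_displacements(ev, lo))

    def test_invalid_threshold(self):
        with pytest.raises(DamageError):
            kinchin_pease_displacements(10.0, 0.0)


class TestNrtScale:
    def test_hand_value_for_water(self):
        # rho N_A Phi_v / M with rho=1, M=18.015, Phi_v=1
        assert nrt_scale(1.0, 1.0, 18.015) == pytest.approx(
            AVOGADRO / 18.015, rel=1e-12)

    def test_linear_in_density(self):
        assert nrt_scale(2.0, 1.0, 18.0) == pytest.approx(2 * nrt_scale(1.0, 1.0, 18.0))

    def test_zero_fluence_constant(self):
        assert nrt_scale(1.0, 0.0, 18.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(DamageError):
            nrt_scale(-1.0, 1.0, 18.0)


class TestDamageEnergy:
    def test_zero_recoil(self, water):
        assert damage_energy(0.0, 8, 16.0, water) == 0.0

    @given(st.floats(1e-2, 1e8))
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_bounded_by_kinetic_energy(self, t, ):
        from ionphantom.materials import packaged_material

        w = packaged_material("W")
        assert 0.0 < damage_energy(t, 8, 15.999, w) <= t

    def test_low_energy_limit_is_full_energy(self, water):
        # convergence is slow (~eps^(1/6)): ~98% at milli-eV recoils
        assert damage_energy(1e-3, 8, 15.999, water) == pytest.approx(1e-3, rel=0.05)
        assert (damage_energy(1e-6, 8, 15.999, water) / 1e-6
                > damage_energy(1e-3, 8, 15.999, water) / 1e-3)

    def test_independent_reevaluation_of_robinson_fit(self, water):
        # oxygen recoil, 10 keV, in water; re-derive with explicit constants
        z1, a1 = 8, 15.999
        z2 = sum(c.atomic_fraction * c.element.Z for c in water.components)
        a2 = water.mean_atomic_mass
        k = (0.0793 * z1 ** (2 / 3) * math.sqrt(z2) * (a1 + a2) ** 1.5
             / ((z1 ** (2 / 3) + z2 ** (2 / 3)) ** 0.75 * a1 ** 1.5 * math.sqrt(a2)))
        e_l = 30.7345 * z1 * z2 * math.sqrt(z1 ** (2 / 3) + z2 ** (2 / 3)) * (a1 + a2) / a2
        eps = 1e4 / e_l
        g = eps + 0.40244 * eps ** 0.75 + 3.4008 * eps ** (1 / 6)
        assert damage_energy(1e4, z1, a1, water) == pytest.approx(
            1e4 / (1 + k * g), rel=1e-12)


class TestRecoilPartition:
    def test_single_element_target_gets_full_share(self):
        c = ElementSpec.from_symbol("C", Ed=28, Es=7.41)
        graphite = Material.from_atomic_fractions("graphite", 2.0, [(c, 1.0)])
        prof = recoil_partition(BeamSpec(100.0), graphite)
        assert prof.per_element_share == {"C": 1.0}

    def test_water_oxygen_absorbs_most_recoil_energy(self, water):
        prof = recoil_partition(BeamSpec(100.0), water)
        shares = prof.per_element_share
        assert shares["O"] + shares["H"] == pytest.approx(1.0, abs=1e-9)
        assert shares["O"] > shares["H"]

    def test_bookkeeping_inequalities(self, water):
        prof = recoil_partition(BeamSpec(100.0), water)
        assert np.all(prof.displacements >= prof.vacancies)
        assert np.all(prof.vacancies >= 0)
        t = prof.totals_per_ion
        assert t["replacements"] == pytest.approx(
            t["displacements"] - t["vacancies"], rel=1e-9)

    def test_totals_scale_with_particle_count(self, water):
        p1 = recoil_partition(BeamSpec(100.0, n_particles=1000), water)
        p2 = recoil_partition(BeamSpec(100.0, n_particles=3000), water)
        assert p2.totals_per_beam["vacancies"] == pytest.approx(
            3 * p1.totals_per_beam["vacancies"], rel=1e-9)

    def test_vacancies_increase_with_beam_energy(self, materials):
        for name in ("W", "ST", "PMMA"):
            v = [recoil_partition(BeamSpec(e), materials[name]).totals_per_ion["vacancies"]
                 for e in (80.0, 140.0)]
            assert v[1] > v[0]

    def test_params_from_material(self, water):
        params = DamageModelParams.from_material(water)
        assert params.Ed == {"O": 28.0, "H": 10.0}
        assert params.Eb["O"] == 3.0


class TestEnergyPartition:
    def test_closure_to_machine_precision(self, water):
        beam = BeamSpec(140.0)
        ion, stored, phonons = energy_partition(beam, water)
        total = beam.energy_per_nucleon * beam.ion_A * 1e6
        assert ion + stored + phonons == pytest.approx(total, abs=total * 1e-12)

    def test_ionization_dominates_at_therapeutic_energies(self, materials):
        for e in (80.0, 140.0):
            ion, _, _ = energy_partition(BeamSpec(e), materials["PMMA"])
            assert ion / (e * 7.0 * 1e6) > 0.99

    def test_phonon_budget_non_negative(self, materials):
        for m in materials.values():
            _, stored, phonons = energy_partition(BeamSpec(100.0), m)
            assert phonons >= 0.0
            assert stored >= 0.0
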