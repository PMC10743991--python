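"""Bragg curves, peak finding, Monte Carlo tracks and straggle estimators."""

import numpy as np
import pytest

from ionphantom.materials import Phantom
from ionphantom.stopping import BeamSpec, csda_range
from ionphantom.transport import (
    DepthProfile,
    TrackEndpointSet,
    TransportError,
    bragg_curve,
    bragg_peak_position,
    lateral_straggle,
    longitudinal_straggle,
    simulate_tracks,
)


def _endpoints(x, y=None, z=None):
    x = np.asarray(x, dtype=float)
    zeros = np.zeros_like(x)
    return TrackEndpointSet(
        x, zeros if y is None else np.asarray(y, dtype=float),
        zeros if z is None else np.asarray(z, dtype=float),
        seed=0, material_name="toy", E0=100.0)


class TestBraggCurve:
    def test_pmma_120_peak_matches_printed(self, materials):
        dp = bragg_curve(BeamSpec(120.0), Phantom(materials["PMMA"]))
        assert bragg_peak_position(dp) == pytest.approx(88.2, rel=0.05)

    def test_water_80_peak_matches_printed(self, water):
        dp = bragg_curve(BeamSpec(80.0), Phantom(water))
        assert bragg_peak_position(dp) == pytest.approx(40.5, rel=0.05)

    def test_peak_dominates_entrance_for_all_materials(self, materials):
        for m in materials.values():
            for e in (80.0, 140.0):
                dp = bragg_curve(BeamSpec(e), Phantom(m))
                entrance = dp.let_eV_per_A[0]
                assert dp.let_eV_per_A.max() >= 3.0 * entrance

    def test_unblurred_peak_sits_at_csda_range(self, water):
        dp = bragg_curve(BeamSpec(100.0), Phantom(water), grid_step=0.05,
                         sigma_override=0.0)
        assert bragg_peak_position(dp) == pytest.approx(
            csda_range(100.0, water), abs=0.05)

    def test_no_dose_beyond_range_plus_4_sigma(self, water):
        dp = bragg_curve(BeamSpec(80.0), Phantom(water))
        tail = dp.let_eV_per_A[dp.depth_mm > csda_range(80.0, water) + 3.0]
        assert np.all(tail == 0.0)

    def test_grid_step_validation(self, water):
        with pytest.raises(TransportError):
            bragg_curve(BeamSpec(80.0), Phantom(water), grid_step=2.0)


class TestPeakFinder:
    def test_max_exactly_at_node(self):
        depth = np.linspace(0.0, 10.0, 101)
        let = np.exp(-0.5 * ((depth - 4.0) / 1.0) ** 2)
        dp = DepthProfile(depth, let, 100.0, "toy")
        assert bragg_peak_position(dp) == pytest.approx(4.0, abs=1e-9)

    def test_parabola_vertex_between_nodes(self):
        depth = np.arange(0.0, 10.0, 0.5)
        vertex = 4.123
        let = 100.0 - (depth - vertex) ** 2
        dp = DepthProfile(depth, let, 100.0, "toy")
        # parabolic refinement is exact for a quadratic
        assert bragg_peak_position(dp) == pytest.approx(vertex, abs=1e-6)

    def test_flat_profile_has_no_peak(self):
        depth = np.linspace(0.0, 5.0, 20)
        with pytest.raises(TransportError, match="no peak"):
            bragg_peak_position(DepthProfile(depth, np.ones_like(depth), 80.0, "toy"))


class TestMonteCarlo:
    def test_deterministic_limit_collapses_to_csda_range(self, water):
        t = simulate_tracks(BeamSpec(140.0, n_particles=8, seed=3), Phantom(water),
                            scattering=False, straggling=False)
        assert np.ptp(t.x) == 0.0
        assert np.all(t.y == 0.0) and np.all(t.z == 0.0)
        assert t.x[0] == pytest.approx(csda_range(140.0, water), rel=1e-3)

    def test_same_seed_reproduces_endpoints(self, water):
        a = simulate_tracks(BeamSpec(100.0, n_particles=500, seed=11), Phantom(water))
        b = simulate_tracks(BeamSpec(100.0, n_particles=500, seed=11), Phantom(water))
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_different_seed_differs(self, water):
        a = simulate_tracks(BeamSpec(100.0, n_particles=500, seed=1), Phantom(water))
        b = simulate_tracks(BeamSpec(100.0, n_particles=500, seed=2), Phantom(water))
        assert not np.array_equal(a.x, b.x)

    def test_mean_projected_range_tracks_csda(self, water):
        t = simulate_tracks(BeamSpec(100.0, n_particles=10_000, seed=5), Phantom(water))
        res = longitudinal_straggle(t)
        assert res.R_p == pytest.approx(csda_range(100.0, water), rel=0.01)
        assert np.all(t.x >= 0)

    def test_longitudinal_spread_matches_bohr_sigma(self, water):
        from ionphantom.stopping import range_straggle_sigma

        t = simulate_tracks(BeamSpec(140.0, n_particles=20_000, seed=7),
                            Phantom(water), scattering=False)
        res = longitudinal_straggle(t)
        assert res.sigma_long == pytest.approx(
            range_straggle_sigma(140.0, water), rel=0.10)


class TestStraggleEstimators:
    def test_longitudinal_hand_arithmetic(self):
        res = longitudinal_straggle(_endpoints([3.0, 4.0, 5.0]))
        assert res.R_p == pytest.approx(4.0)
        assert res.sigma_long == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-4)

    def test_zero_variance(self):
        res = longitudinal_straggle(_endpoints([2.0, 2.0, 2.0]))
        assert res.sigma_long == 0.0

    def test_population_divisor_not_sample(self):
        # divisor N: sample convention would give sqrt(1.0) here
        res = longitudinal_straggle(_endpoints([3.0, 4.0, 5.0]))
        assert res.sigma_long < 1.0

    def test_lateral_hand_arithmetic(self):
        t = _endpoints([1.0, 1.0], y=[1.0, 3.0], z=[1.0, 1.0])
        assert lateral_straggle(t) == pytest.approx(np.sqrt((1.0 + 4.0) / 2.0), rel=1e-12)

    def test_lateral_on_axis_is_zero(self):
        assert lateral_straggle(_endpoints([1.0, 2.0])) == 0.0

    def test_gaussian_sampling_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(5.0, 0.3, size=100_000)
        res = longitudinal_straggle(_endpoints(x))
        assert res.sigma_long == pytest.approx(0.3, rel=0.02)

    def test_lateral_gaussian_reduction_factor(self):
        # for y, z ~ N(0, s): E[((|y|+|z|)/2)^2] = s^2 (1 + 2/pi)/2
        rng = np.random.default_rng(1)
        s = 0.8
        y = rng.normal(0, s, 200_000)
        z = rng.normal(0, s, 200_000)
        expected = s * np.sqrt((1.0 + 2.0 / np.pi) / 2.0)
        assert lateral_straggle(_endpoints(np.ones_like(y), y=y, z=z)) == pytest.approx(
            expected, rel=0.01)
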