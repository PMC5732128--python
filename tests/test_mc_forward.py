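import math

import numpy as np
import pytest

from pinrecon import physics
from pinrecon.geometry import CameraGeometry, PinholeUnit
from pinrecon.mc_forward import (
    PhotonState,
    SimulationConfig,
    forced_direction_sample,
    forward_project,
    pinhole_transmission,
    record_spectrum,
    trace_through_phantom,
)
from pinrecon.mlem import allocate_histories
from pinrecon.phantoms import DensityMap, VoxelGrid, make_sphere, uniform_air_density


def _point_source_histories(grid, center, n):
    act = make_sphere(grid, center, 1e-3, 1.0)
    return allocate_histories(act, n)


class TestForcedDirection:
    def test_closed_form_weight(self, single_unit, rng):
        # r = 150 mm to the pinhole at (0, 0, 180): source on the axis at z = 30
        _, w = forced_direction_sample([0.0, 0.0, 30.0], single_unit, rng)
        expected = 0.5 * (1.0 - 150.0 / math.sqrt(150.0**2 + 10.0**2))
        assert w == pytest.approx(expected, rel=1e-12)
        assert w == pytest.approx(1.108e-3, rel=1e-3)

    def test_weight_vanishes_with_aperture(self, rng):
        unit = PinholeUnit(theta=0.0, phi=0.0, aperture_diameter=1e-6)
        _, w = forced_direction_sample([0.0, 0.0, 0.0], unit, rng)
        assert w < 1e-13

    def test_directions_stay_inside_cone(self, single_unit, rng):
        p = np.array([20.0, -10.0, 0.0])
        v = single_unit.pinhole_center - p
        r = np.linalg.norm(v)
        cos_max = r / math.sqrt(r**2 + (2 * single_unit.aperture_diameter) ** 2)
        for _ in range(200):
            d, _ = forced_direction_sample(p, single_unit, rng)
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)
            assert float(d @ (v / r)) >= cos_max - 1e-12

    def test_emission_at_pinhole_rejected(self, single_unit, rng):
        with pytest.raises(ValueError):
            forced_direction_sample(single_unit.pinhole_center, single_unit, rng)


class TestTrace:
    def test_zero_density_photon_exits_unchanged(self, tables, rng):
        grid = VoxelGrid(15, 4.0)
        dens = DensityMap(grid, np.zeros(grid.shape))
        photon = PhotonState([0.0, 0.0, -20.0], [0.0, 0.0, 1.0], weight=0.7)
        out = trace_through_phantom(photon, dens, tables, rng)
        assert out is not None
        np.testing.assert_allclose(out.direction, [0, 0, 1])
        assert out.energy == pytest.approx(physics.EMISSION_ENERGY_KEV)
        assert out.weight == pytest.approx(0.7)
        assert out.position[2] >= grid.extent / 2 - 1e-9

    def test_water_slab_survival_matches_beer_lambert(self, tables, rng):
        """No-interaction fraction through x mm of water equals exp(-mu x) (3 sigma)."""
        grid = VoxelGrid(10, 4.0)
        dens = uniform_air_density(grid)
        # 20-mm water slab spanning z voxels 2..6
        dens.values[:, :, 2:7] = 1.0
        dens.material[:, :, 2:7] = physics.WATER
        mu = tables.mu_linear(physics.WATER, physics.EMISSION_ENERGY_KEV, 1.0)
        p_surv = math.exp(-mu * 20.0)
        n = 40_000
        survived = 0
        for _ in range(n):
            photon = PhotonState([0.0, 0.0, -19.9], [0.0, 0.0, 1.0])
            out = trace_through_phantom(photon, dens, tables, rng)
            if out is not None and out.energy == pytest.approx(physics.EMISSION_ENERGY_KEV):
                survived += 1
        sigma = math.sqrt(n * p_surv * (1 - p_surv))
        assert abs(survived - n * p_surv) < 3 * sigma

    def test_layered_slabs_multiply_exponentials(self, tables, rng):
        """Transmission through stacked layers equals the product of exponentials."""
        grid = VoxelGrid(10, 4.0)
        dens = uniform_air_density(grid)
        dens.values[:, :, 2:4] = 1.0
        dens.material[:, :, 2:4] = physics.WATER
        dens.values[:, :, 6:8] = 0.5
        dens.material[:, :, 6:8] = physics.WATER
        mu = tables.mu_linear(physics.WATER, physics.EMISSION_ENERGY_KEV, 1.0)
        p_surv = math.exp(-mu * 8.0) * math.exp(-mu * 0.5 * 8.0)
        n = 40_000
        survived = 0
        for _ in range(n):
            photon = PhotonState([0.0, 0.0, -19.9], [0.0, 0.0, 1.0])
            out = trace_through_phantom(photon, dens, tables, rng)
            if out is not None and out.energy == pytest.approx(physics.EMISSION_ENERGY_KEV):
                survived += 1
        sigma = math.sqrt(n * p_surv * (1 - p_surv))
        assert abs(survived - n * p_surv) < 3 * sigma

    def test_non_finite_photon_rejected(self, tables, rng):
        grid = VoxelGrid(5, 4.0)
        dens = uniform_air_density(grid)
        photon = PhotonState([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        photon.position[0] = np.inf
        with pytest.raises(ValueError):
            trace_through_phantom(photon, dens, tables, rng)


class TestPinholeTransmission:
    def test_ray_through_aperture_center(self, single_unit):
        photon = PhotonState([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        assert pinhole_transmission(photon, single_unit) == 1.0

    def test_miss_without_penetration_blocks(self, single_unit):
        # parallel ray 1 mm outside the aperture edge
        photon = PhotonState([3.5, 0.0, 0.0], [0.0, 0.0, 1.0])
        assert pinhole_transmission(photon, single_unit, penetration_enabled=False) == 0.0

    def test_penetration_monotone_in_miss_distance(self, single_unit):
        values = []
        for x in (2.6, 3.0, 4.0, 6.0):
            photon = PhotonState([x, 0.0, 0.0], [0.0, 0.0, 1.0])
            values.append(pinhole_transmission(photon, single_unit, penetration_enabled=True))
        assert all(0 < v < 1 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))


@pytest.fixture(scope="module")
def air35():
    grid = VoxelGrid(35, 4.0)
    return grid, uniform_air_density(grid)


class TestForwardProject:
    def test_point_source_matches_analytic_sensitivity(self, air35, tables,
                                                       single_unit_geometry):
        """Expected counts follow d^2 cos^3(alpha) / (16 h^2) for a point source."""
        grid, dens = air35
        cfg = SimulationConfig(n_histories=100_000, seed=5, energy_resolution_fwhm=0.0)
        d, h = 5.0, 180.0
        for offset in (0.0, 40.0):
            hist = _point_source_histories(grid, (offset, 0.0, 0.0), cfg.n_histories)
            ps = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
            cos_a = h / math.sqrt(h * h + offset * offset)
            expected = 1e6 * 60.0 * physics.PHOTONS_PER_DECAY * d * d * cos_a**3 / (16 * h * h)
            # analytic primaries are nearly noise-free; 1% covers air attenuation
            assert ps.counts.sum() == pytest.approx(expected, rel=0.01)

    def test_linear_in_activity(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 20_000)
        cfg = SimulationConfig(n_histories=20_000, seed=9)
        a = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        b = forward_project(hist, 2.0, 60.0, single_unit_geometry, dens, tables, cfg)
        np.testing.assert_allclose(b.counts, 2.0 * a.counts, rtol=1e-12)

    def test_total_invariant_to_history_count(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        totals = []
        for n in (30_000, 120_000):
            hist = _point_source_histories(grid, (10, -14, 6), n)
            cfg = SimulationConfig(n_histories=n, seed=11)
            totals.append(
                forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg).counts.sum()
            )
        assert totals[1] == pytest.approx(totals[0], rel=0.02)

    def test_reproducible_bit_for_bit(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 10_000)
        cfg = SimulationConfig(n_histories=10_000, seed=21)
        a = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        b = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_detected_weight_bounded_by_emitted(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 10_000)
        cfg = SimulationConfig(n_histories=10_000, seed=2)
        ps = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        assert 0 < ps.detected_weight <= ps.emitted_weight

    def test_history_budget_mismatch_rejected(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 500)
        cfg = SimulationConfig(n_histories=900, seed=1)
        with pytest.raises(ValueError):
            forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        with pytest.raises(ValueError):
            forward_project(np.zeros_like(hist), 1.0, 60.0, single_unit_geometry, dens,
                            tables, SimulationConfig(n_histories=1))

    def test_poisson_sampling_integer_counts(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 20_000)
        cfg = SimulationConfig(n_histories=20_000, seed=4, poisson_sampling=True)
        ps = forward_project(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        assert np.all(ps.counts == np.round(ps.counts))


class TestForcedVsAnalog:
    def test_estimators_agree_in_scatter_free_medium(self, tables):
        """Forced (analytic primary + cone) and analog totals agree within 3 sigma."""
        grid = VoxelGrid(15, 4.0)
        dens = uniform_air_density(grid)
        unit = PinholeUnit(theta=0.0, phi=0.0, R=60.0, H=40.0, aperture_diameter=20.0,
                           n_pix=32, pixel_pitch=78.7 / 32)
        geom = CameraGeometry(units=(unit,))
        hist = _point_source_histories(grid, (0, 0, 0), 50_000)
        cfg_f = SimulationConfig(n_histories=50_000, seed=31, energy_resolution_fwhm=0.0)
        forced = forward_project(hist, 1.0, 60.0, geom, dens, tables, cfg_f)

        n_analog = 400_000
        hist_a = _point_source_histories(grid, (0, 0, 0), n_analog)
        totals = []
        for rep in range(3):
            cfg_a = SimulationConfig(
                n_histories=n_analog, seed=600 + rep, forced=False,
                energy_resolution_fwhm=0.0,
            )
            totals.append(
                forward_project(hist_a, 1.0, 60.0, geom, dens, tables, cfg_a).counts.sum()
            )
        analog_mean = float(np.mean(totals))
        # each analog detection carries weight `scale`; hit counts are ~binomial
        scale = 1e6 * 60.0 * physics.PHOTONS_PER_DECAY / n_analog
        mean_hits = analog_mean / scale
        sigma_mean = scale * math.sqrt(mean_hits) / math.sqrt(len(totals))
        assert forced.counts.sum() == pytest.approx(analog_mean, abs=3 * sigma_mean)


class TestSpectrum:
    def test_photopeak_only_without_scatter(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 20_000)
        cfg = SimulationConfig(
            n_histories=20_000, seed=8, max_scatter_order=0, energy_resolution_fwhm=0.0,
        )
        spec = record_spectrum(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        nonzero = np.nonzero(spec.counts)[0]
        np.testing.assert_array_equal(nonzero, [140])

    def test_total_matches_windowless_counts(self, air35, tables, single_unit_geometry):
        grid, dens = air35
        hist = _point_source_histories(grid, (0, 0, 0), 20_000)
        cfg = SimulationConfig(
            n_histories=20_000, seed=8, energy_window=(0.0, 1e9),
            energy_resolution_fwhm=0.0,
        )
        spec = record_spectrum(hist, 1.0, 60.0, single_unit_geometry, dens, tables, cfg)
        assert spec.total == pytest.approx(spec.projections.counts.sum(), rel=1e-9)

    def test_water_increases_subphotopeak_fraction(self, tables):
        """Object scatter fills the continuum below the photopeak."""
        grid = VoxelGrid(25, 4.0)
        unit = PinholeUnit(theta=0.0, phi=0.0, R=120.0, H=80.0, aperture_diameter=12.0)
        geom = CameraGeometry(units=(unit,))
        act = make_sphere(grid, (0, 0, 0), 9.0, 1.0)
        hist = allocate_histories(act, 60_000)
        cfg = SimulationConfig(n_histories=60_000, seed=13, energy_window=(0.0, 1e9),
                               energy_resolution_fwhm=0.0)
        fractions = {}
        for name, water in (("air", False), ("water", True)):
            dens = uniform_air_density(grid)
            if water:
                dens.values[:] = 1.0
                dens.material[:] = physics.WATER
            spec = record_spectrum(hist, 1.0, 60.0, geom, dens, tables, cfg)
            below = spec.counts[:130].sum()
            fractions[name] = below / spec.total
        assert fractions["water"] > 5 * fractions["air"]
        assert fractions["water"] > 0.005
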