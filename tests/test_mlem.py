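import numpy as np
import pytest

from pinrecon import physics
from pinrecon.geometry import CameraGeometry, PinholeUnit, default_arc_geometry
from pinrecon.mc_forward import ProjectionSet, SimulationConfig, forward_project
from pinrecon.mlem import (
    DualMatrixMLEM,
    ReconstructionConfig,
    allocate_histories,
    reconstruct,
)
from pinrecon.phantoms import ActivityMap, VoxelGrid, make_sphere, uniform_air_density


class TestAllocateHistories:
    def test_equal_voxels_split_evenly(self):
        assert list(allocate_histories(np.array([1.0, 1.0]), 10)) == [5, 5]

    def test_largest_remainder_by_hand(self):
        assert list(allocate_histories(np.array([0.7, 0.3]), 3)) == [2, 1]

    def test_sum_equals_budget_for_random_maps(self, rng):
        for _ in range(200):
            values = rng.exponential(1.0, size=rng.integers(2, 60))
            budget = int(rng.integers(1, 10_000))
            out = allocate_histories(values, budget)
            assert out.sum() == budget
            assert np.all(out >= 0)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError):
            allocate_histories(np.zeros(4), 10)

    def test_preserves_shape(self):
        values = np.ones((3, 3, 3))
        assert allocate_histories(values, 27).shape == (3, 3, 3)


@pytest.fixture(scope="module")
def small_system(tables):
    grid = VoxelGrid(9, 4.0)
    geom = default_arc_geometry(K=3)
    density = uniform_air_density(grid)
    return grid, geom, density


class TestEmUpdate:
    def test_exact_data_is_a_fixed_point(self, small_system, tables):
        """measured == simulated => unit ratios => the estimate does not move."""
        grid, geom, density = small_system
        cfg = ReconstructionConfig(
            n_iterations=1, histories_per_iteration=200_000, seed=3, ratio_epsilon=1e-9
        )
        engine = DualMatrixMLEM(geom, density, tables, cfg)
        state = engine.initial_state()
        sim_cfg = engine._iteration_sim_config(state.iteration)
        measured = forward_project(
            state.history_map, state.activity.total, 60.0, geom, density, tables, sim_cfg
        )
        new_state = engine.em_update(state, measured)
        # voxels whose back-projection pixels were all realized by the finite
        # history sample reproduce exactly; the rest can only lose the tiny
        # weight of unrealized pixels
        matrix = engine.bp.matrix.tocsr()
        q_flat = measured.counts.ravel()
        hit = q_flat > 0
        exact = np.ones(grid.N**3, dtype=bool)
        for j in range(grid.N**3):
            cols = matrix.indices[matrix.indptr[j]:matrix.indptr[j + 1]]
            if cols.size and not np.all(hit[cols]):
                exact[j] = False
        exact = exact.reshape(grid.shape) & (state.activity.values > 0)
        assert exact.sum() > 0.5 * (state.activity.values > 0).sum()
        np.testing.assert_allclose(
            new_state.activity.values[exact], state.activity.values[exact], rtol=1e-12
        )
        assert new_state.activity.values[~exact].sum() <= state.activity.values[~exact].sum() * (1 + 1e-12)
        assert new_state.activity.total == pytest.approx(state.activity.total, rel=5e-3)

    def test_single_voxel_single_pixel_converges_in_one_update(self, tables):
        """Degenerate 1x1 system: one update lands on p/a within the MC noise."""
        unit = PinholeUnit(theta=0.0, phi=0.0, R=100.0, H=50.0, aperture_diameter=6.0,
                           n_pix=1, pixel_pitch=200.0)
        geom = CameraGeometry(units=(unit,))
        grid = VoxelGrid(1, 4.0)
        density = uniform_air_density(grid)
        p_value = 5000.0
        measured = ProjectionSet(
            counts=np.full((1, 1, 1), p_value), acquisition_time=60.0,
            energy_window=(126.45, 154.55),
        )
        cfg = ReconstructionConfig(n_iterations=1, histories_per_iteration=50_000, seed=5)
        result = reconstruct(measured, geom, density, tables, cfg)
        # counts per MBq from the same forward model
        probe = ActivityMap(grid, np.ones((1, 1, 1)))
        sim = forward_project(
            allocate_histories(probe, 50_000), 1.0, 60.0, geom, density, tables,
            SimulationConfig(n_histories=50_000, seed=99),
        )
        expected = p_value / sim.counts.sum()
        assert result.state.activity.total == pytest.approx(expected, rel=0.02)

    def test_nonnegative_output(self, small_system, tables, rng):
        grid, geom, density = small_system
        cfg = ReconstructionConfig(n_iterations=2, histories_per_iteration=20_000, seed=7)
        measured = ProjectionSet(
            counts=rng.uniform(0, 50, (3, 32, 32)), acquisition_time=60.0,
            energy_window=(126.45, 154.55),
        )
        result = reconstruct(measured, geom, density, tables, cfg)
        assert np.all(result.state.activity.values >= 0)

    def test_shape_mismatch_rejected(self, small_system, tables):
        grid, geom, density = small_system
        cfg = ReconstructionConfig(n_iterations=1, histories_per_iteration=1000, seed=1)
        engine = DualMatrixMLEM(geom, density, tables, cfg)
        bad = ProjectionSet(
            counts=np.ones((2, 32, 32)), acquisition_time=60.0, energy_window=(0.0, 1e9)
        )
        with pytest.raises(ValueError):
            engine.em_update(engine.initial_state(), bad)


class TestReconstruct:
    def test_zero_iterations_returns_uniform_initial(self, small_system, tables):
        grid, geom, density = small_system
        cfg = ReconstructionConfig(n_iterations=0, histories_per_iteration=1000, seed=1,
                                   initial_total_activity=2.0)
        measured = ProjectionSet(
            counts=np.ones((3, 32, 32)), acquisition_time=60.0, energy_window=(0.0, 1e9)
        )
        result = reconstruct(measured, geom, density, tables, cfg)
        assert result.state.iteration == 0
        assert result.state.activity.total == pytest.approx(2.0)
        inside = result.state.activity.values > 0
        assert np.unique(result.state.activity.values[inside]).size == 1

    def test_deterministic_given_seed(self, small_system, tables):
        grid, geom, density = small_system
        measured = ProjectionSet(
            counts=np.full((3, 32, 32), 3.0), acquisition_time=60.0,
            energy_window=(126.45, 154.55),
        )
        cfg = ReconstructionConfig(n_iterations=3, histories_per_iteration=20_000, seed=17)
        a = reconstruct(measured, geom, density, tables, cfg)
        b = reconstruct(measured, geom, density, tables, cfg)
        np.testing.assert_array_equal(a.state.activity.values, b.state.activity.values)
        np.testing.assert_array_equal(a.state.history_map, b.state.history_map)

    def test_history_map_sums_to_budget_every_iteration(self, small_system, tables):
        grid, geom, density = small_system
        budgets = []
        measured = ProjectionSet(
            counts=np.full((3, 32, 32), 3.0), acquisition_time=60.0,
            energy_window=(126.45, 154.55),
        )
        cfg = ReconstructionConfig(n_iterations=3, histories_per_iteration=12_345, seed=2)
        result = reconstruct(
            measured, geom, density, tables, cfg,
            callback=lambda s: budgets.append(int(s.history_map.sum())),
        )
        assert budgets == [12_345] * 3

    def test_total_activity_increments_settle(self, small_system, tables):
        """On noise-free self-consistent data the iteration increments shrink."""
        grid, geom, density = small_system
        truth = make_sphere(grid, (0, 0, 0), 4.0, 1.0)
        measured = forward_project(
            allocate_histories(truth, 400_000), truth.total, 60.0, geom, density,
            tables, SimulationConfig(n_histories=400_000, seed=55),
        )
        cfg = ReconstructionConfig(n_iterations=12, histories_per_iteration=100_000, seed=3)
        result = reconstruct(measured, geom, density, tables, cfg)
        totals = [rec["total_activity_mbq"] for rec in result.log]
        early = abs(totals[1] - totals[0])
        late = max(abs(b - a) for a, b in zip(totals[-4:], totals[-3:]))
        assert late < early
        assert totals[-1] == pytest.approx(1.0, rel=0.05)
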