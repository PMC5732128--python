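"""Dual-matrix ML-EM reconstruction.

Classical ML-EM updates the estimate f by

    f_new_j = f_old_j / sum_i a_ij * sum_i a_ij * p_i / sum_k a_ik f_old_k,

with a_ij the probability that a decay in voxel j is detected in pixel i.
Here the two appearances of the system matrix are deliberately different
(dual-matrix form): the denominator projection sum_k a_ik f_old_k is
computed by the Monte Carlo forward-projector, while the outer sums use
the analytical ray-tracing back-projector b_ij,

    f_new_j = f_old_j / sum_i b_ij * sum_i b_ij * p_i / q_i,
    q = MC-forward(f_old).

The estimate is stored as two coupled datasets: a float activity volume in
MBq, and an integer history map whose entries sum to the per-iteration
history budget and are apportioned proportionally to the activity.  The
forward simulation emits exactly those histories with weights tied to the
absolute activity, so projected counts and activity stay in a fixed
relationship through all iterations -- absolute quantification without any
calibration factor.

Dual-matrix updates forfeit the ML-EM monotone-likelihood guarantee; a
Poisson log-likelihood proxy is logged per iteration for observation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backprojector import RayTracingBackprojector
from .geometry import CameraGeometry
from .mc_forward import ProjectionSet, SimulationConfig, forward_project
from .phantoms import ActivityMap, DensityMap
from .physics import PhysicsTables

__all__ = [
    "ReconstructionConfig",
    "ReconstructionState",
    "ReconstructionResult",
    "allocate_histories",
    "DualMatrixMLEM",
    "em_update",
    "reconstruct",
]


@dataclass(frozen=True)
class ReconstructionConfig:
    """Reconstruction settings.

    ``histories_per_iteration`` is the Monte Carlo budget of each forward
    projection (a desk-scale default; larger budgets reduce the noise the
    finite sampling injects into the update ratios).  ``ratio_epsilon``
    guards the pixel ratios p/q: q is floored at ratio_epsilon times the
    mean nonzero simulated pixel value, so empty simulated pixels cannot
    produce infinite ratios.  ``initial_total_activity`` is spread
    uniformly over the in-FOV voxels as the first estimate; the
    multiplicative update rescales the magnitude within a few iterations.
    """

    n_iterations: int = 20
    histories_per_iteration: int = 100_000
    seed: int = 0
    ratio_epsilon: float = 1e-3
    initial_total_activity: float = 1.0
    post_filter: str | None = None  # None | "gaussian" | "butterworth"
    post_filter_params: tuple = ()

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.ratio_epsilon <= 0:
            raise ValueError("ratio_epsilon must be > 0")


@dataclass
class ReconstructionState:
    """Float activity estimate (MBq) paired with its integer history map."""

    activity: ActivityMap
    history_map: np.ndarray
    iteration: int = 0

    def __post_init__(self):
        self.history_map = np.asarray(self.history_map, dtype=np.int64)
        if self.history_map.shape != self.activity.grid.shape:
            raise ValueError("history map shape must match the activity grid")


@dataclass
class ReconstructionResult:
    state: ReconstructionState
    log: list
    filtered: ActivityMap | None = None


def allocate_histories(activity, budget: int) -> np.ndarray:
    """Apportion an integer history budget proportionally to activity.

    Largest-remainder apportionment: every voxel gets the floor of its
    exact quota and the leftover histories go to the largest fractional
    remainders (ties broken by voxel index), so the result is deterministic
    and sums to the budget exactly.
    """
    values = getattr(activity, "values", activity)
    flat = np.asarray(values, dtype=np.float64).ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("total activity must be positive")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    quota = budget * (flat / total)
    base = np.floor(quota).astype(np.int64)
    remaining = budget - int(base.sum())
    if remaining > 0:
        frac = quota - base
        top = np.argsort(-frac, kind="stable")[:remaining]
        base[top] += 1
    return base.reshape(np.asarray(values).shape)


class DualMatrixMLEM:
    """Reconstruction engine binding the MC forward and ray-tracing backward models."""

    def __init__(
        self,
        geometry: CameraGeometry,
        density: DensityMap,
        tables: PhysicsTables,
        config: ReconstructionConfig,
        sim_config: SimulationConfig | None = None,
        backprojector: RayTracingBackprojector | None = None,
    ):
        self.geometry = geometry
        self.density = density
        self.tables = tables
        self.config = config
        self.grid = density.grid
        self.sim_template = sim_config or SimulationConfig(
            n_histories=config.histories_per_iteration
        )
        self.bp = backprojector or RayTracingBackprojector(geometry, self.grid)
        self.sensitivity = self.bp.sensitivity()
        self._sens_pos = self.sensitivity > 0

    def initial_state(self) -> ReconstructionState:
        """Uniform positive first estimate over the in-FOV voxels."""
        grid = self.grid
        x, y, z = grid.center_mesh()
        radius = min(self.geometry.fov_diameter, grid.extent) / 2.0
        fov = (x**2 + y**2 + z**2 <= radius**2) & self._sens_pos
        if not fov.any():
            raise ValueError("no voxels inside the field of view")
        values = np.zeros(grid.shape)
        values[fov] = self.config.initial_total_activity / fov.sum()
        activity = ActivityMap(grid, values)
        return ReconstructionState(
            activity=activity,
            history_map=allocate_histories(activity, self.config.histories_per_iteration),
            iteration=0,
        )

    def _iteration_sim_config(self, iteration: int) -> SimulationConfig:
        return replace(
            self.sim_template,
            n_histories=self.config.histories_per_iteration,
            seed=int(self.config.seed + iteration),
            poisson_sampling=False,
        )

    def em_update(self, state: ReconstructionState, measured: ProjectionSet) -> ReconstructionState:
        """One dual-matrix iteration."""
        new_state, _q = self._em_update_with_projections(state, measured)
        return new_state

    def _em_update_with_projections(self, state, measured):
        expected = (self.geometry.K, self.geometry.n_pix, self.geometry.n_pix)
        if measured.counts.shape != expected:
            raise ValueError("measured projections do not match the geometry")
        total = state.activity.total
        if total <= 0:
            raise ValueError("estimate has no activity left")
        sim_cfg = self._iteration_sim_config(state.iteration)
        simulated = forward_project(
            state.history_map, total, measured.acquisition_time,
            self.geometry, self.density, self.tables, sim_cfg,
        )
        q = simulated.counts
        positive = q > 0
        if not positive.any():
            raise ValueError("all simulated projections are zero")
        floor = self.config.ratio_epsilon * q[positive].mean()
        ratio = measured.counts / np.maximum(q, floor)
        back = self.bp.backproject(ratio).volume
        f_new = np.zeros_like(state.activity.values)
        mask = self._sens_pos
        f_new[mask] = state.activity.values[mask] * back[mask] / self.sensitivity[mask]
        activity = ActivityMap(self.grid, f_new)
        new_state = ReconstructionState(
            activity=activity,
            history_map=allocate_histories(activity, self.config.histories_per_iteration),
            iteration=state.iteration + 1,
        )
        return new_state, q

    def run(self, measured: ProjectionSet, callback=None) -> ReconstructionResult:
        state = self.initial_state()
        log = []
        for _it in range(self.config.n_iterations):
            state, q = self._em_update_with_projections(state, measured)
            log.append(
                {
                    "iteration": state.iteration,
                    "total_activity_mbq": state.activity.total,
                    "loglik_proxy": _poisson_loglik_proxy(measured.counts, q),
                }
            )
            if callback is not None:
                callback(state)
        filtered = self._post_filter(state)
        return ReconstructionResult(state=state, log=log, filtered=filtered)

    def _post_filter(self, state: ReconstructionState) -> ActivityMap | None:
        if self.config.post_filter is None:
            return None
        from . import analysis

        if self.config.post_filter == "gaussian":
            out = analysis.gaussian_post_filter(state.activity.values, *self.config.post_filter_params)
        elif self.config.post_filter == "butterworth":
            out = analysis.butterworth_filter(
                state.activity.values, *self.config.post_filter_params, voxel_mm=self.grid.m
            )
        else:
            raise ValueError(f"unknown post filter {self.config.post_filter!r}")
        return ActivityMap(self.grid, np.maximum(out, 0.0))


def _poisson_loglik_proxy(p, q):
    """Poisson log-likelihood proxy sum_i (p_i log q_i - q_i).

    Observational only: with the finite-history forward model the update is
    not guaranteed to increase it monotonically.
    """
    q = np.maximum(np.asarray(q, dtype=float), 1e-30)
    p = np.asarray(p, dtype=float)
    return float(np.sum(p * np.log(q) - q))


def em_update(
    state: ReconstructionState,
    measured: ProjectionSet,
    geometry: CameraGeometry,
    density: DensityMap,
    tables: PhysicsTables,
    config: ReconstructionConfig,
    sim_config: SimulationConfig | None = None,
) -> ReconstructionState:
    """Functional single-iteration interface (builds the engine each call)."""
    engine = DualMatrixMLEM(geometry, density, tables, config, sim_config)
    return engine.em_update(state, measured)


def reconstruct(
    measured: ProjectionSet,
    geometry: CameraGeometry,
    density: DensityMap,
    tables: PhysicsTables,
    config: ReconstructionConfig,
    sim_config: SimulationConfig | None = None,
    callback=None,
) -> ReconstructionResult:
    """Run a full reconstruction from the uniform initial estimate.

    Iteration i seeds its forward simulation with ``config.seed + i`` so
    runs are reproducible and iterations independent.  The optional post
    filter is applied to a copy; the returned state is unfiltered.
    """
    engine = DualMatrixMLEM(geometry, density, tables, config, sim_config)
    return engine.run(measured, callback=callback)
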