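"""Analytical ray-tracing back-projector.

The backward system model deliberately ignores everything the Monte Carlo
forward model works hard to include: it assumes (a) no attenuation or
scatter in the object, (b) an infinitesimally small aperture without
penetration, and (c) detection efficiency independent of incidence angle.
This asymmetric pairing of an accurate forward model with an approximate
backward model is the dual-matrix strategy: the forward model carries the
quantitative burden, the back-projector only redistributes ratio images
into the volume.

For a voxel centred at P and a unit k, the detector intercept of the ray
through the pinhole is spread over an n_grid x n_grid cell-centred lattice
of width G_D = m * M (the voxel footprint under magnification M).  The
lattice resolution follows the heuristic

    n_grid = floor(2 + 60 / (1 + (R - z')^0.8) + 0.5),   (R - z') in cm,

which is bounded by [2, 62] and decreases with voxel-to-pinhole distance
to mimic the distance-dependent pinhole sensitivity at bounded cost.  The
back-projection probability of pixel i for voxel j is the number of lattice
points landing in pixel i divided by sum_k n_grid(j,k)^2 over all units the
voxel lies in front of (points falling off the active detector area count
in the denominator but contribute nothing: the default, following the
normalization above; ``denominator="on_detector"`` switches to counting
only points that landed on detectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .geometry import CameraGeometry, DegenerateVoxelError, PinholeUnit, project_to_detector
from .phantoms import VoxelGrid

__all__ = [
    "grid_size",
    "SamplingGrid",
    "BackprojectionResult",
    "build_sampling_grid",
    "RayTracingBackprojector",
    "backproject",
    "sensitivity_map",
]

#: conversion from mm (world units) to the cm the grid heuristic expects
MM_TO_CM = 0.1


def grid_size(distance_cm: float) -> int:
    """Linear lattice dimension for a voxel at the given pinhole distance (cm).

    Evaluates floor(2 + 60 / (1 + distance^0.8) + 0.5); round-half-up, range
    exactly [2, 62], non-increasing in distance.
    """
    if distance_cm < 0:
        raise ValueError("distance must be >= 0")
    return _kernels._grid_size(float(distance_cm))


@dataclass(frozen=True)
class SamplingGrid:
    """Cell-centred detector-plane lattice for one voxel-unit pair."""

    n_grid: int
    width: float
    center: tuple[float, float]
    points: np.ndarray  # (n_grid**2, 2) detector-plane coordinates, mm


@dataclass
class BackprojectionResult:
    """Back-projected volume plus the per-voxel lattice-point denominator."""

    volume: np.ndarray
    denominator_map: np.ndarray


def build_sampling_grid(
    voxel_center, unit: PinholeUnit, m: float, distance_scale: float = MM_TO_CM
) -> SamplingGrid:
    """Sampling lattice of one voxel on one detector.

    The lattice is centred on the perspective intercept of the voxel
    centre, has width m*M, and n_grid points per side at cell-centred
    offsets ((i + 0.5)/n - 0.5) * width.  Raises for voxels at or behind
    the pinhole plane.
    """
    icpt = project_to_detector(voxel_center, unit)  # raises DegenerateVoxelError
    z_prime = icpt.rotated[2]
    n = grid_size((unit.R - z_prime) * distance_scale)
    width = m * icpt.magnification
    offsets = ((np.arange(n) + 0.5) / n - 0.5) * width
    gx, gy = np.meshgrid(icpt.x_d + offsets, icpt.y_d + offsets, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    return SamplingGrid(n_grid=n, width=width, center=(icpt.x_d, icpt.y_d), points=points)


class RayTracingBackprojector:
    """Cached sparse back-projection operator for one geometry and grid.

    The operator is iteration-independent, so its sparse matrix (voxels x
    detector pixels) is built once and reused; the sensitivity map
    sum_i b_ij is the operator applied to unit-valued projections.
    """

    def __init__(
        self,
        geometry: CameraGeometry,
        grid: VoxelGrid,
        distance_scale: float = MM_TO_CM,
        denominator: str = "all",
    ):
        if denominator not in ("all", "on_detector"):
            raise ValueError("denominator must be 'all' or 'on_detector'")
        self.geometry = geometry
        self.grid = grid
        self.distance_scale = distance_scale
        self.denominator = denominator

        K = geometry.K
        npix = geometry.n_pix
        rot = np.stack([u.rotation for u in geometry])
        Rv = np.array([u.R for u in geometry])
        Hv = np.array([u.H for u in geometry])
        pitch = np.array([u.pixel_pitch for u in geometry])
        rows, cols, vals, denom = _kernels._bp_entries(
            grid.N, grid.m, rot, Rv, Hv, pitch, npix,
            distance_scale, denominator == "on_detector",
        )
        self._denom = denom
        nvox = grid.N**3
        with np.errstate(divide="ignore", invalid="ignore"):
            weights = np.where(denom[cols] > 0, vals / denom[cols], 0.0)
        self.matrix = sp.coo_matrix(
            (weights, (cols, rows)), shape=(nvox, K * npix * npix)
        ).tocsr()
        self._sensitivity: np.ndarray | None = None

    @property
    def denominator_map(self) -> np.ndarray:
        return self._denom.reshape(self.grid.shape)

    def backproject(self, projections) -> BackprojectionResult:
        """Spread projection-space values back into the volume (Eq. form b^T r)."""
        values = getattr(projections, "counts", projections)
        values = np.asarray(values, dtype=np.float64)
        expected = (self.geometry.K, self.geometry.n_pix, self.geometry.n_pix)
        if values.shape != expected:
            raise ValueError(f"projections shape {values.shape} != geometry shape {expected}")
        vol = self.matrix @ values.ravel()
        return BackprojectionResult(
            volume=vol.reshape(self.grid.shape), denominator_map=self.denominator_map
        )

    def sensitivity(self) -> np.ndarray:
        """Per-voxel sum_i b_ij; 1 for voxels fully seen by every unit, 0 for blind ones."""
        if self._sensitivity is None:
            ones = np.ones((self.geometry.K, self.geometry.n_pix, self.geometry.n_pix))
            self._sensitivity = self.backproject(ones).volume
        return self._sensitivity


@lru_cache(maxsize=8)
def _cached_operator(geometry, grid, distance_scale, denominator):
    return RayTracingBackprojector(geometry, grid, distance_scale, denominator)


def backproject(
    projections,
    geometry: CameraGeometry,
    grid: VoxelGrid,
    distance_scale: float = MM_TO_CM,
    denominator: str = "all",
) -> BackprojectionResult:
    """One-shot back-projection (operator cached across calls)."""
    op = _cached_operator(geometry, grid, distance_scale, denominator)
    return op.backproject(projections)


def sensitivity_map(
    geometry: CameraGeometry,
    grid: VoxelGrid,
    distance_scale: float = MM_TO_CM,
    denominator: str = "all",
) -> np.ndarray:
    """Per-voxel back-projector sensitivity sum_i b_ij."""
    op = _cached_operator(geometry, grid, distance_scale, denominator)
    return op.sensitivity()
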