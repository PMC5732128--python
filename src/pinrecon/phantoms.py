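"""Voxelized activity and density phantoms for emission-imaging studies.

All generators place material by voxel-centre inclusion (a voxel belongs to
a shape iff its centre does; no partial-volume weighting) and are
deterministic.  World coordinates are millimetres with the origin at the
grid centre; the centre of voxel ``i`` along an axis is
``(i - (N - 1) / 2) * m``, so voxel ``i`` covers the half-open interval
``[(i - N/2) m, (i + 1 - N/2) m)``.

Activity maps carry MBq per voxel; density maps carry g/cm^3 plus a
per-voxel material label (air or water) that selects the attenuation
tables during transport.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import physics

__all__ = [
    "VoxelGrid",
    "ActivityMap",
    "DensityMap",
    "sphere_radius_mm",
    "make_sphere",
    "NEMA_SPHERE_VOLUMES_ML",
    "nema_sphere_centers",
    "make_nema_spheres_in_torso",
    "point_grid_positions",
    "make_point_source_grid",
    "make_cardiac_phantom",
    "density_from_attenuation",
    "uniform_air_density",
]

#: NEMA image-quality sphere set (mL)
NEMA_SPHERE_VOLUMES_ML = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class VoxelGrid:
    """Cubic voxel grid: N voxels per side of length m (mm)."""

    N: int
    m: float

    def __post_init__(self):
        if self.N < 1 or self.m <= 0:
            raise ValueError("need N >= 1 and m > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.N, self.N, self.N)

    @property
    def extent(self) -> float:
        """Total side length N*m (mm)."""
        return self.N * self.m

    def axis_centers(self) -> np.ndarray:
        return (np.arange(self.N) - (self.N - 1) / 2.0) * self.m

    def center_mesh(self):
        c = self.axis_centers()
        return np.meshgrid(c, c, c, indexing="ij")

    def voxel_center(self, index) -> np.ndarray:
        return (np.asarray(index, dtype=float) - (self.N - 1) / 2.0) * self.m

    def nearest_index(self, point) -> tuple[int, int, int]:
        idx = np.rint(np.asarray(point, dtype=float) / self.m + (self.N - 1) / 2.0)
        if np.any(idx < 0) or np.any(idx >= self.N):
            raise ValueError(f"point {point} outside the grid")
        return tuple(int(i) for i in idx)

    @property
    def voxel_volume_ml(self) -> float:
        return self.m**3 / 1000.0


@dataclass
class ActivityMap:
    """Per-voxel activity in MBq on a cubic grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")
        if np.any(self.values < 0):
            raise ValueError("activity must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "ActivityMap":
        return ActivityMap(self.grid, self.values.copy())

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "ActivityMap":
        return cls(grid, np.zeros(grid.shape))


@dataclass
class DensityMap:
    """Per-voxel density (g/cm^3) plus material label (air or water)."""

    grid: VoxelGrid
    values: np.ndarray
    material: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")
        if self.material is None:
            self.material = np.full(self.grid.shape, physics.AIR, dtype=np.uint8)
        self.material = np.asarray(self.material, dtype=np.uint8)
        if self.material.shape != self.grid.shape:
            raise ValueError("material shape must match the grid")


def uniform_air_density(grid: VoxelGrid) -> DensityMap:
    """Non-attenuating surroundings: air density everywhere."""
    return DensityMap(
        grid,
        np.full(grid.shape, physics.DENSITY_G_CM3[physics.AIR]),
        np.full(grid.shape, physics.AIR, dtype=np.uint8),
    )


def sphere_radius_mm(volume_ml: float) -> float:
    """Radius (mm) of a sphere of the given volume (mL = cm^3)."""
    return 10.0 * (3.0 * volume_ml / (4.0 * math.pi)) ** (1.0 / 3.0)


def make_sphere(
    grid: VoxelGrid, center, volume_ml: float, activity_mbq: float
) -> ActivityMap:
    """Uniform sphere of the given volume and total activity.

    Voxels whose centres fall inside the sphere share the activity equally;
    a sphere smaller than one voxel degenerates to a single-voxel source at
    the nearest voxel.  The stated total is met exactly by construction.
    """
    center = np.asarray(center, dtype=float)
    radius = sphere_radius_mm(volume_ml)
    half = grid.extent / 2.0
    if np.any(np.abs(center) + radius > half):
        raise ValueError("sphere extends outside the grid")
    x, y, z = grid.center_mesh()
    mask = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
    values = np.zeros(grid.shape)
    if not mask.any():
        values[grid.nearest_index(center)] = activity_mbq
    else:
        values[mask] = activity_mbq / mask.sum()
    return ActivityMap(grid, values)


def nema_sphere_centers(
    ring_radius: float = 50.0, tilt: float = math.pi / 4
) -> list[tuple[float, np.ndarray]]:
    """(volume_ml, centre) for the six NEMA spheres on a tilted mounting ring.

    The spheres sit at equal angular spacing on a circle of ``ring_radius``
    in a plane tilted by ``tilt`` about the x-axis (emulating a mounting
    disk aligned with the cardiac short-axis plane).
    """
    e_u = np.array([1.0, 0.0, 0.0])
    e_v = np.array([0.0, math.cos(tilt), math.sin(tilt)])
    out = []
    for i, vol in enumerate(NEMA_SPHERE_VOLUMES_ML):
        a = 2.0 * math.pi * i / len(NEMA_SPHERE_VOLUMES_ML)
        center = ring_radius * (math.cos(a) * e_u + math.sin(a) * e_v)
        out.append((vol, center))
    return out


def make_nema_spheres_in_torso(
    grid: VoxelGrid,
    concentration_mbq_ml: float,
    water_filled: bool = True,
    ring_radius: float = 50.0,
    tilt: float = math.pi / 4,
    torso_semi_axes: tuple[float, float] = (150.0, 100.0),
) -> tuple[ActivityMap, DensityMap]:
    """Six NEMA spheres at equal concentration inside an elliptical torso.

    Sphere i holds ``concentration * volume_i`` MBq exactly.  The torso is
    an elliptical cylinder (default semi-axes 150 x 100 mm, axial length
    covering the grid) filled with water or air; sphere voxels are always
    water-equivalent.
    """
    x, y, z = grid.center_mesh()
    a, b = torso_semi_axes
    torso = (x / a) ** 2 + (y / b) ** 2 <= 1.0

    density = np.full(grid.shape, physics.DENSITY_G_CM3[physics.AIR])
    material = np.full(grid.shape, physics.AIR, dtype=np.uint8)
    if water_filled:
        density[torso] = physics.DENSITY_G_CM3[physics.WATER]
        material[torso] = physics.WATER

    values = np.zeros(grid.shape)
    for vol, center in nema_sphere_centers(ring_radius, tilt):
        radius = sphere_radius_mm(vol)
        mask = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
        if not mask.any():
            mask = np.zeros(grid.shape, dtype=bool)
            mask[grid.nearest_index(center)] = True
        values[mask] += concentration_mbq_ml * vol / mask.sum()
        density[mask] = physics.DENSITY_G_CM3[physics.WATER]
        material[mask] = physics.WATER

    return ActivityMap(grid, values), DensityMap(grid, density, material)


def point_grid_positions(n_per_side: int, spacing: float) -> list[np.ndarray]:
    """True positions of a cubic measurement grid centred on the origin.

    Ordered by itertools.product over (x, y, z) offsets, x slowest.
    """
    offsets = (np.arange(n_per_side) - (n_per_side - 1) / 2.0) * spacing
    return [np.array(p) for p in itertools.product(offsets, offsets, offsets)]


def make_point_source_grid(
    grid: VoxelGrid, n_per_side: int = 5, spacing: float = 20.0, activity_mbq: float = 1.0
) -> list[ActivityMap]:
    """One single-voxel source per position of an n^3 cubic grid.

    Each true position is assigned to its nearest voxel; positions must all
    fall inside the voxel grid.  Returns maps in the order of
    :func:`point_grid_positions`.
    """
    maps = []
    for pos in point_grid_positions(n_per_side, spacing):
        values = np.zeros(grid.shape)
        values[grid.nearest_index(pos)] = activity_mbq  # raises if outside
        maps.append(ActivityMap(grid, values))
    return maps


def _cardiac_masks(grid: VoxelGrid, a_outer, a_inner, c_outer, c_inner, base_z):
    x, y, z = grid.center_mesh()
    rho2 = x**2 + y**2
    below = z <= base_z
    outer = below & (rho2 / a_outer**2 + ((z - base_z) / c_outer) ** 2 <= 1.0)
    inner = below & (rho2 / a_inner**2 + ((z - base_z) / c_inner) ** 2 <= 1.0)
    return outer & ~inner, inner


def make_cardiac_phantom(
    grid: VoxelGrid,
    myocardial_activity_mbq: float = 21.1,
    torso_water: bool = False,
    wall_thickness: float = 10.3,
    cavity_width: float = 38.0,
    shell_volume_ml: float = 120.0,
    torso_semi_axes: tuple[float, float] = (150.0, 100.0),
) -> tuple[ActivityMap, DensityMap]:
    """Half-ellipsoid myocardial shell around a water-filled ventricle.

    The ventricular cavity is a half-ellipsoid of transverse width
    ``cavity_width``; the myocardium is the surrounding shell of uniform
    wall thickness.  The outer long semi-axis is first solved in closed
    form for the continuous shell volume and then refined by a
    deterministic scan so the voxelized shell volume best matches the
    target (within 5% on practical grids).  Activity is uniform over the
    shell; the cavity is always water, the torso water or air by flag.
    """
    a_inner = cavity_width / 2.0
    a_outer = a_inner + wall_thickness
    target_mm3 = shell_volume_ml * 1000.0
    # continuous-shell solution: (2*pi/3) * [(ao^2 - ai^2) c_o + ai^2 * wall] = V
    c_outer0 = (3.0 * target_mm3 / (2.0 * math.pi) - a_inner**2 * wall_thickness) / (
        a_outer**2 - a_inner**2
    )

    best = None
    for dc in np.arange(-16.0, 16.0 + 1e-9, 0.5):
        c_outer = c_outer0 + dc
        c_inner = c_outer - wall_thickness
        if c_inner <= 0 or c_outer >= grid.extent - grid.m:
            continue
        base_z = c_outer / 2.0  # centre the long axis on the grid
        shell, _ = _cardiac_masks(grid, a_outer, a_inner, c_outer, c_inner, base_z)
        err = abs(shell.sum() * grid.voxel_volume_ml - shell_volume_ml)
        if best is None or err < best[0]:
            best = (err, c_outer)
    if best is None:
        raise ValueError("grid too small for the cardiac phantom")
    c_outer = best[1]
    c_inner = c_outer - wall_thickness
    base_z = c_outer / 2.0
    shell, cavity = _cardiac_masks(grid, a_outer, a_inner, c_outer, c_inner, base_z)

    values = np.zeros(grid.shape)
    values[shell] = myocardial_activity_mbq / shell.sum()

    x, y, _ = grid.center_mesh()
    a, b = torso_semi_axes
    torso = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    density = np.full(grid.shape, physics.DENSITY_G_CM3[physics.AIR])
    material = np.full(grid.shape, physics.AIR, dtype=np.uint8)
    if torso_water:
        density[torso] = physics.DENSITY_G_CM3[physics.WATER]
        material[torso] = physics.WATER
    for mask in (shell, cavity):
        density[mask] = physics.DENSITY_G_CM3[physics.WATER]
        material[mask] = physics.WATER

    return ActivityMap(grid, values), DensityMap(grid, density, material)


def density_from_attenuation(
    grid: VoxelGrid,
    mu_map,
    reference_energy_kev: float = physics.EMISSION_ENERGY_KEV,
    tables: "physics.PhysicsTables | None" = None,
) -> DensityMap:
    """Rescale a linear-attenuation map (1/mm) into a density map.

    density = mu / mu_water(E) with mu_water the linear attenuation of
    unit-density water at the reference energy; linear and monotonic.
    Voxels above 5% of water density are labelled water, the rest air.
    """
    mu = np.asarray(mu_map, dtype=float)
    if mu.shape != grid.shape:
        raise ValueError("mu_map shape must match the grid")
    if np.any(mu < 0):
        raise ValueError("attenuation coefficients must be >= 0")
    mu_w = physics.water_mu_linear(reference_energy_kev, tables)
    density = mu / mu_w
    material = np.where(density > 0.05, physics.WATER, physics.AIR).astype(np.uint8)
    return DensityMap(grid, density, material)
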