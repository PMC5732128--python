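"""Monte Carlo forward-projector.

Transports photon histories from an integer per-voxel history map through
the density map and the pinholes onto the detectors.  This operator is the
system matrix of the reconstruction in operational form: it is never
materialized, and because every history carries the weight

    activity_total [MBq] * 1e6 [decays/s/MBq] * acquisition_time [s]
                  * photons_per_decay / n_histories

the projections come out in absolute expected counts.  That absolute
counts-to-activity relationship is what makes the reconstruction
calibration-free: no measured calibration factor enters anywhere.

Variance reduction, per history and unit:

* the unscattered (primary) contribution is scored analytically: a point
  is sampled on the aperture disc and the exact flux weight
  cos(theta) * area / (4 pi s^2), times the deterministic attenuation
  exp(-tau) along the line of sight, is binned at the ray's detector
  intercept -- no pass/fail or survival sampling, so primaries are
  essentially noise-free;
* the scattered (and optional knife-edge penetration) contribution uses
  direction forcing: the emission direction is drawn from the cone
  subtending a disc of diameter four times the aperture diameter centred
  on the pinhole, with compensating weight Omega/4pi, and the photon is
  traced through Compton scatter inside the object.

A forced photon is scored only on the unit it was forced toward, so the
forcing captures the small-angle scatter reaching that unit but
under-samples large-angle cross-unit scatter (an inherent property of the
technique).  Both contributions are exactly unbiased for their part of
the physics, and their sum matches an analog (isotropic) simulation in
expectation for scatter-free media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels, physics
from .geometry import CameraGeometry, PinholeUnit
from .phantoms import DensityMap

__all__ = [
    "PhotonState",
    "SimulationConfig",
    "ProjectionSet",
    "Spectrum",
    "forced_direction_sample",
    "trace_through_phantom",
    "pinhole_transmission",
    "forward_project",
    "record_spectrum",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PhotonState:
    """Photon in flight: position (mm), unit direction, energy (keV), weight."""

    position: np.ndarray
    direction: np.ndarray
    energy: float = physics.EMISSION_ENERGY_KEV
    weight: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("direction must be a unit vector")
        if not (0 < self.energy <= physics.EMISSION_ENERGY_KEV + 1e-9):
            raise ValueError("energy must be in (0, emission energy]")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one Monte Carlo projection run.

    ``energy_resolution_fwhm`` is the detector FWHM in percent at the
    140.5-keV photopeak (0 = ideal); the default window is the photopeak
    +/- 10%.  ``forced`` switches the direction-forcing variance reduction;
    analog (isotropic) emission exists for unbiasedness checks.
    """

    n_histories: int
    seed: int = 0
    max_scatter_order: int = 8
    penetration_enabled: bool = False
    energy_resolution_fwhm: float = 6.0
    poisson_sampling: bool = False
    energy_window: tuple[float, float] = (126.45, 154.55)
    forced: bool = True
    photons_per_decay: float = physics.PHOTONS_PER_DECAY
    energy_cutoff: float = 10.0
    penetration_half_angle: float = math.pi / 4

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")

    @property
    def energy_sigma(self) -> float:
        return (
            self.energy_resolution_fwhm / 100.0
        ) * physics.EMISSION_ENERGY_KEV * _FWHM_TO_SIGMA


@dataclass
class ProjectionSet:
    """K detector count images plus the acquisition metadata.

    ``counts`` holds expected counts (or Poisson samples when requested) in
    a K x n_pix x n_pix array; absolute scale, no calibration factor.
    """

    counts: np.ndarray
    acquisition_time: float
    energy_window: tuple[float, float]
    histories_used: int = 0
    emitted_weight: float = 0.0
    detected_weight: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("counts must be K x n x n")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def K(self) -> int:
        return self.counts.shape[0]


@dataclass
class Spectrum:
    """Deposited-energy histogram (1-keV bins) before window selection."""

    energies: np.ndarray  # bin centres, keV
    counts: np.ndarray
    projections: ProjectionSet

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def _geometry_arrays(geometry: CameraGeometry):
    K = geometry.K
    ph = np.empty((K, 3))
    ax = np.empty((K, 3))
    dc = np.empty((K, 3))
    dn = np.empty((K, 3))
    du = np.empty((K, 3))
    dv = np.empty((K, 3))
    Rv = np.empty(K)
    aper = np.empty(K)
    pitch = np.empty(K)
    cmu = np.empty(K)
    for k, unit in enumerate(geometry):
        ph[k] = unit.pinhole_center
        ax[k] = unit.axis
        dc[k] = unit.detector_center
        normal, ub, vb = unit.detector_frame()
        dn[k], du[k], dv[k] = normal, ub, vb
        Rv[k] = unit.R
        aper[k] = unit.aperture_diameter
        pitch[k] = unit.pixel_pitch
        cmu[k] = unit.collimator_mu
    return ph, ax, dc, dn, du, dv, Rv, aper, pitch, cmu


def forced_direction_sample(emission_point, unit: PinholeUnit, rng: np.random.Generator):
    """Sample an emission direction forced toward one pinhole.

    The direction is uniform over the solid angle of the cone subtending a
    disc of diameter ``4 * aperture_diameter`` centred at the pinhole and
    perpendicular to the line of sight; the returned weight is
    Omega / 4pi = (1 - r / sqrt(r^2 + (2 d)^2)) / 2 with r the
    emission-to-pinhole distance and d the aperture diameter.
    """
    p = np.asarray(emission_point, dtype=float)
    v = unit.pinhole_center - p
    r = float(np.linalg.norm(v))
    if r < 1e-9:
        raise ValueError("emission point coincides with the pinhole centre")
    rad = 2.0 * unit.aperture_diameter
    cosbmax = r / math.sqrt(r * r + rad * rad)
    weight = 0.5 * (1.0 - cosbmax)
    cb = 1.0 - rng.random() * (1.0 - cosbmax)
    sb = math.sqrt(max(0.0, 1.0 - cb * cb))
    az = 2.0 * math.pi * rng.random()
    l = v / r
    b1x, b1y, b1z, b2x, b2y, b2z = _kernels._perp_basis(l[0], l[1], l[2])
    b1 = np.array([b1x, b1y, b1z])
    b2 = np.array([b2x, b2y, b2z])
    direction = cb * l + sb * (math.cos(az) * b1 + math.sin(az) * b2)
    return direction, weight


def trace_through_phantom(
    photon: PhotonState,
    density: DensityMap,
    tables: physics.PhysicsTables,
    rng: np.random.Generator,
    max_order: int = 8,
    energy_cutoff: float = 10.0,
):
    """Transport one photon through the voxelized phantom.

    Returns the exiting :class:`PhotonState` (weight preserved) or ``None``
    if the photon was absorbed (photoelectric, energy cutoff, or scatter
    order exhausted).
    """
    if not (np.all(np.isfinite(photon.position)) and np.all(np.isfinite(photon.direction))):
        raise ValueError("photon state must be finite")
    log_e, log_pe, log_inc = tables.kernel_arrays()
    state = np.uint64(rng.integers(1, 2**63))
    pe_buf = np.empty(log_pe.shape[0])
    inc_buf = np.empty(log_pe.shape[0])
    exited, x, y, z, dx, dy, dz, energy, _state, _ns = _kernels._trace(
        photon.position[0], photon.position[1], photon.position[2],
        photon.direction[0], photon.direction[1], photon.direction[2],
        photon.energy, state,
        density.material, density.values, density.grid.N, density.grid.m,
        log_e, log_pe, log_inc, max_order, energy_cutoff, pe_buf, inc_buf,
    )
    if not exited:
        return None
    return PhotonState(
        position=np.array([x, y, z]),
        direction=np.array([dx, dy, dz]),
        energy=energy,
        weight=photon.weight,
    )


def pinhole_transmission(
    photon: PhotonState,
    unit: PinholeUnit,
    penetration_enabled: bool = False,
    half_angle: float = math.pi / 4,
) -> float:
    """Transmission factor of the aperture for a photon heading toward it.

    1 inside the aperture disc; outside, either 0 (perfect collimation) or
    the knife-edge penetration factor exp(-mu * chord) with the chord
    through a wedge of the given half opening angle.
    """
    axis = unit.axis
    dn = float(photon.direction @ axis)
    if dn <= 1e-12:
        return 0.0
    t = (unit.R - float(photon.position @ axis)) / dn
    if t < 0:
        return 0.0
    q = photon.position + t * photon.direction - unit.pinhole_center
    miss = float(np.linalg.norm(q))
    if miss <= 0.5 * unit.aperture_diameter:
        return 1.0
    if not penetration_enabled:
        return 0.0
    chord = 2.0 * (miss - 0.5 * unit.aperture_diameter) / math.tan(half_angle)
    return math.exp(-unit.collimator_mu * chord)


def _run_kernel(
    history_map, activity_total, time_s, geometry, density, tables, config,
    record_spec: bool, n_spec_bins: int = 180,
):
    hist = np.asarray(history_map)
    if hist.shape != density.grid.shape:
        raise ValueError("history map shape must match the density grid")
    flat = hist.reshape(-1).astype(np.int64)
    total_hist = int(flat.sum())
    if total_hist == 0:
        raise ValueError("history map is empty")
    if total_hist != config.n_histories:
        raise ValueError(
            f"history map sums to {total_hist}, configured n_histories is {config.n_histories}"
        )
    nz = np.nonzero(flat)[0]
    src_idx = nz.astype(np.int64)
    src_cnt = flat[nz]

    ph, ax, dc, dn, du, dv, Rv, aper, pitch, cmu = _geometry_arrays(geometry)
    log_e, log_pe, log_inc = tables.kernel_arrays()
    npix = geometry.n_pix
    out = np.zeros((geometry.K, npix, npix))
    spec = np.zeros(n_spec_bins if record_spec else 1)

    weight_scale = (
        activity_total * 1e6 * time_s * config.photons_per_decay / config.n_histories
    )
    emitted, detected = _kernels._forward(
        src_idx, src_cnt, density.grid.N, density.grid.m,
        ph, ax, dc, dn, du, dv,
        Rv, aper, pitch, npix,
        cmu, config.penetration_enabled, math.tan(config.penetration_half_angle),
        density.material, density.values, log_e, log_pe, log_inc,
        tables.emission_energy, config.energy_window[0], config.energy_window[1],
        config.energy_sigma,
        config.max_scatter_order, config.energy_cutoff, config.forced,
        weight_scale, config.seed,
        out, spec, record_spec,
    )
    if config.poisson_sampling:
        rng = np.random.default_rng(np.uint64(_kernels._splitmix64(np.uint64(config.seed))))
        out = rng.poisson(out).astype(np.float64)
    ps = ProjectionSet(
        counts=out,
        acquisition_time=time_s,
        energy_window=config.energy_window,
        histories_used=config.n_histories,
        emitted_weight=emitted,
        detected_weight=detected,
    )
    return ps, spec


def forward_project(
    history_map,
    activity_total: float,
    time_s: float,
    geometry: CameraGeometry,
    density: DensityMap,
    tables: physics.PhysicsTables,
    config: SimulationConfig,
) -> ProjectionSet:
    """Simulate projections of the integer history map in absolute counts.

    Each history is drawn from the history map (uniform inside its voxel),
    forced toward each pinhole in turn, traced through the phantom, tested
    against the aperture, propagated to the detector, energy-window
    weighted and binned.  Output is in expected counts for the given total
    activity and acquisition time; ``config.poisson_sampling`` replaces the
    expectation by one Poisson realization.
    """
    ps, _ = _run_kernel(
        history_map, activity_total, time_s, geometry, density, tables, config,
        record_spec=False,
    )
    return ps


def record_spectrum(
    history_map,
    activity_total: float,
    time_s: float,
    geometry: CameraGeometry,
    density: DensityMap,
    tables: physics.PhysicsTables,
    config: SimulationConfig,
    n_bins: int = 180,
) -> Spectrum:
    """Deposited-energy spectrum of all detected photons (1-keV bins).

    The histogram ignores the energy window (the window only weights the
    binned projection counts), so its total equals the window-less detected
    count total; the photopeak sits in the 140-141 keV bin, the object
    scatter forms the continuum below.
    """
    ps, spec = _run_kernel(
        history_map, activity_total, time_s, geometry, density, tables, config,
        record_spec=True, n_spec_bins=n_bins,
    )
    return Spectrum(energies=np.arange(n_bins) + 0.5, counts=spec, projections=ps)
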