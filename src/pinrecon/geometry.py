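"""Multi-pinhole camera geometry and source-to-detector transforms.

The camera is a static ring of K pinhole-detector units.  Each unit has a
pinhole axis that runs through the source-volume origin; the axis direction
is given by a polar angle ``theta`` and an azimuthal angle ``phi``.  The
pinhole sits at distance ``R`` from the origin along the axis and the
detector plane lies a further ``H`` behind it.  A source point projects
through the (idealized, infinitesimal) pinhole onto the detector as a
mirrored image scaled by the magnification ``M = H / (R - z')``, where
``z'`` is the source coordinate along the pinhole axis.

Conventions: right-handed world frame with its origin at the source-volume
centre, millimetres throughout, angles in radians.  The frame rotation that
aligns the pinhole axis with +z' is the composite rotation about the x- and
y-axes

    [x']   [ cos(phi)  sin(phi)sin(theta)  sin(phi)cos(theta)] [x]
    [y'] = [    0          cos(theta)         -sin(theta)    ] [y]
    [z']   [-sin(phi)  cos(phi)sin(theta)  cos(phi)cos(theta)] [z]

so the unit's axis direction in world coordinates is the third row read as
a vector, ``(-sin(phi), cos(phi)sin(theta), cos(phi)cos(theta))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DegenerateVoxelError",
    "PinholeUnit",
    "CameraGeometry",
    "DetectorIntercept",
    "rotation_matrix",
    "rotate_to_pinhole_frame",
    "pinhole_axis",
    "magnification",
    "project_to_detector",
    "detector_pixel_index",
    "default_arc_geometry",
    "save_geometry",
    "load_geometry",
]

DETECTOR_WIDTH_MM = 78.7
DEFAULT_N_PIX = 32
DEFAULT_PITCH_MM = DETECTOR_WIDTH_MM / DEFAULT_N_PIX


class DegenerateVoxelError(ValueError):
    """A source point lies at or behind the pinhole plane (z' >= R)."""


def rotation_matrix(theta: float, phi: float) -> np.ndarray:
    """3x3 proper rotation taking world coordinates to the pinhole frame."""
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    return np.array(
        [
            [cp, sp * st, sp * ct],
            [0.0, ct, -st],
            [-sp, cp * st, cp * ct],
        ]
    )


def rotate_to_pinhole_frame(point: Sequence[float], theta: float, phi: float) -> np.ndarray:
    """Express a world point in the pinhole frame (z' along the pinhole axis)."""
    p = np.asarray(point, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 3-vector")
    return rotation_matrix(theta, phi) @ p


def pinhole_axis(theta: float, phi: float) -> np.ndarray:
    """Unit vector along the pinhole axis (the world direction mapped to +z')."""
    return rotation_matrix(theta, phi).T @ np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class PinholeUnit:
    """One pinhole-detector unit of the camera.

    Parameters
    ----------
    theta, phi
        Polar and azimuthal angle of the pinhole axis (radians).
    R
        Origin-to-pinhole distance (mm).
    H
        Pinhole-to-detector distance (mm).
    aperture_diameter
        Pinhole opening diameter (mm); only the forward model sees it.
    n_pix, pixel_pitch
        Detector elements per side and element size (mm).
    detector_tilt
        Angle between detector normal and pinhole axis (radians); the tilt
        is about the detector-plane x' axis.  Only the forward model
        honours it -- the back-projector always assumes a perpendicular
        detector.
    collimator_mu
        Linear attenuation of the aperture material at the photopeak
        (1/mm); used only when knife-edge penetration is enabled.
    """

    theta: float
    phi: float
    R: float = 180.0
    H: float = 120.0
    aperture_diameter: float = 5.0
    n_pix: int = DEFAULT_N_PIX
    pixel_pitch: float = DEFAULT_PITCH_MM
    detector_tilt: float = 0.0
    collimator_mu: float = 3.0

    def __post_init__(self):
        if not (self.R > 0 and self.H > 0):
            raise ValueError("R and H must be positive")
        if self.aperture_diameter < 0:
            raise ValueError("aperture_diameter must be >= 0")
        if self.n_pix < 1 or self.pixel_pitch <= 0:
            raise ValueError("detector needs n_pix >= 1 and pixel_pitch > 0")

    @property
    def detector_width(self) -> float:
        """Active detector width, n_pix * pixel_pitch (mm)."""
        return self.n_pix * self.pixel_pitch

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.theta, self.phi)

    @property
    def axis(self) -> np.ndarray:
        return pinhole_axis(self.theta, self.phi)

    @property
    def pinhole_center(self) -> np.ndarray:
        return self.R * self.axis

    @property
    def detector_center(self) -> np.ndarray:
        return (self.R + self.H) * self.axis

    def detector_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(normal, u-basis, v-basis) of the detector plane in world coords.

        For an untilted unit the normal is the pinhole axis and the in-plane
        bases are the rotated x'/y' directions; a tilt rotates normal and
        v-basis about the u-basis.
        """
        rot = self.rotation
        e1, e2, axis = rot[0], rot[1], rot[2]
        ct, st = math.cos(self.detector_tilt), math.sin(self.detector_tilt)
        normal = ct * axis + st * e2
        v_basis = ct * e2 - st * axis
        return normal, e1, v_basis


@dataclass(frozen=True)
class CameraGeometry:
    """Ordered collection of pinhole-detector units.

    The unit order defines the projection index k in 0..K-1.  All units
    must share one detector matrix size so projection sets stack into a
    K x n_pix x n_pix array.
    """

    units: tuple[PinholeUnit, ...]
    fov_diameter: float = 190.0

    def __post_init__(self):
        if len(self.units) < 1:
            raise ValueError("a camera needs at least one unit")
        if len({u.n_pix for u in self.units}) != 1:
            raise ValueError("all units must share one detector matrix size")

    @property
    def K(self) -> int:
        return len(self.units)

    @property
    def n_pix(self) -> int:
        return self.units[0].n_pix

    def __iter__(self) -> Iterator[PinholeUnit]:
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class DetectorIntercept:
    """Perspective projection of one source point through a pinhole."""

    x_d: float
    y_d: float
    magnification: float
    rotated: tuple[float, float, float]


def magnification(z_prime: float, R: float, H: float) -> float:
    """Pinhole magnification M = H / (R - z') for a point at axis depth z'."""
    if z_prime >= R:
        raise DegenerateVoxelError(
            f"source point at z'={z_prime:g} mm lies at or behind the pinhole plane (R={R:g} mm)"
        )
    return H / (R - z_prime)


def project_to_detector(point: Sequence[float], unit: PinholeUnit) -> DetectorIntercept:
    """Project a world point through the pinhole onto the detector plane.

    Returns the mirrored, magnified intercept ``(x_d, y_d) = (-M x', -M y')``.
    """
    rotated = rotate_to_pinhole_frame(point, unit.theta, unit.phi)
    m = magnification(rotated[2], unit.R, unit.H)
    return DetectorIntercept(
        x_d=-m * rotated[0],
        y_d=-m * rotated[1],
        magnification=m,
        rotated=(rotated[0], rotated[1], rotated[2]),
    )


def detector_pixel_index(x_d: float, y_d: float, unit: PinholeUnit):
    """Map detector-plane coordinates to a (row, col) pixel bin, or None.

    The n_pix x n_pix grid is centred on the pinhole-axis intercept; bins
    are half-open with the floor convention, so the plane origin (0, 0)
    falls in pixel (n_pix//2, n_pix//2) and a point exactly on a pixel
    boundary belongs to the pixel whose lower edge it is.  Rows follow
    y_d, columns x_d.  Returns None outside the active area.
    """
    col = math.floor(x_d / unit.pixel_pitch + unit.n_pix / 2.0)
    row = math.floor(y_d / unit.pixel_pitch + unit.n_pix / 2.0)
    if 0 <= row < unit.n_pix and 0 <= col < unit.n_pix:
        return (row, col)
    return None


def default_arc_geometry(
    K: int = 19,
    R: float = 180.0,
    H: float = 120.0,
    aperture: float = 5.0,
    n_pix: int = DEFAULT_N_PIX,
    pixel_pitch: float = DEFAULT_PITCH_MM,
    fov_diameter: float = 190.0,
) -> CameraGeometry:
    """Synthetic 180-degree transaxial arc of K identical units.

    Pinhole axes are placed at equally spaced polar angles spanning 180
    degrees in the y-z plane (phi = 0); K = 1 puts the single unit on the
    +z axis.  Deterministic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        thetas = [0.0]
    else:
        thetas = [-math.pi / 2 + i * math.pi / (K - 1) for i in range(K)]
    units = tuple(
        PinholeUnit(
            theta=t, phi=0.0, R=R, H=H, aperture_diameter=aperture,
            n_pix=n_pix, pixel_pitch=pixel_pitch,
        )
        for t in thetas
    )
    return CameraGeometry(units=units, fov_diameter=fov_diameter)


# ---------------------------------------------------------------------------
# flat-text geometry configuration (one [unit] block per pinhole)

_UNIT_KEYS = {
    "theta_deg": ("theta", math.radians),
    "phi_deg": ("phi", math.radians),
    "r_mm": ("R", float),
    "h_mm": ("H", float),
    "aperture_mm": ("aperture_diameter", float),
    "n_pix": ("n_pix", int),
    "pitch_mm": ("pixel_pitch", float),
    "tilt_deg": ("detector_tilt", math.radians),
    "collimator_mu_per_mm": ("collimator_mu", float),
}


def save_geometry(geometry: CameraGeometry, path) -> None:
    lines = ["# pinrecon camera geometry", f"fov_mm = {geometry.fov_diameter!r}"]
    for u in geometry:
        lines.append("[unit]")
        lines.append(f"theta_deg = {math.degrees(u.theta)!r}")
        lines.append(f"phi_deg = {math.degrees(u.phi)!r}")
        lines.append(f"R_mm = {u.R!r}")
        lines.append(f"H_mm = {u.H!r}")
        lines.append(f"aperture_mm = {u.aperture_diameter!r}")
        lines.append(f"n_pix = {u.n_pix}")
        lines.append(f"pitch_mm = {u.pixel_pitch!r}")
        lines.append(f"tilt_deg = {math.degrees(u.detector_tilt)!r}")
        lines.append(f"collimator_mu_per_mm = {u.collimator_mu!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_geometry(path) -> CameraGeometry:
    fov = 190.0
    units: list[PinholeUnit] = []
    fields: dict | None = None

    def flush():
        nonlocal fields
        if fields is not None:
            units.append(PinholeUnit(**fields))
            fields = None

    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "[unit]":
            flush()
            fields = {"theta": 0.0, "phi": 0.0}
            continue
        if "=" not in line:
            raise ValueError(f"malformed geometry line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        key = key.lower()
        if fields is None:
            if key == "fov_mm":
                fov = float(value)
            else:
                raise ValueError(f"unknown top-level geometry key: {key!r}")
        else:
            if key not in _UNIT_KEYS:
                raise ValueError(f"unknown unit key: {key!r}")
            name, conv = _UNIT_KEYS[key]
            fields[name] = conv(float(value)) if conv in (math.radians,) else conv(value)
    flush()
    return CameraGeometry(units=tuple(units), fov_diameter=fov)
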