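"""Quantification and image-quality analyses.

Covers the activity recovery coefficients used for sphere phantoms, the
plane-distance procedure that probes the spatial integrity of point-source
reconstructions, averaged line profiles, the standard post-reconstruction
filters (fixed-kernel Gaussian, radial 3-D Butterworth) and display helpers
(maximum-intensity projections, mask dilation).

The activity recovery coefficient of a volume of interest (VOI) is

    ARC = A_E / A_R,

the estimated over the reference activity.  Two VOI conventions are used:
the physical sphere diameter (ARC), and the physical diameter plus 8 mm --
two voxel lengths -- to also collect the counts displaced by the finite
spatial resolution (total activity recovery coefficient, TARC).

All operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import VoxelGrid

__all__ = [
    "RecoveryResult",
    "PlaneDistanceResult",
    "spherical_voi_mask",
    "recovery_coefficient",
    "gaussian_post_filter",
    "plane_distance_analysis",
    "line_profile",
    "butterworth_filter",
    "mip",
    "dilate_mask",
]

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class RecoveryResult:
    """Estimated vs reference activity in one VOI."""

    A_E: float
    A_R: float
    coefficient: float
    voi_kind: str = "physical"


@dataclass
class PlaneDistanceResult:
    """Adjacent-plane distances per axis from reconstructed point sources.

    ``mean_mm[axis]`` holds the distances between the mean coordinates of
    adjacent planes orthogonal to that axis; ``std_mm[axis]`` the standard
    deviations of the per-point coordinate differences between the paired
    points of the two planes.
    """

    mean_mm: dict
    std_mm: dict

    def max_abs_error(self, true_spacing_mm: float) -> float:
        return max(
            float(np.max(np.abs(np.asarray(v) - true_spacing_mm)))
            for v in self.mean_mm.values()
        )

    def max_std(self) -> float:
        return max(float(np.max(v)) for v in self.std_mm.values())


def _volume_of(v) -> np.ndarray:
    return np.asarray(getattr(v, "values", v), dtype=float)


def spherical_voi_mask(grid: VoxelGrid, center, diameter: float) -> np.ndarray:
    """Boolean voxel mask of a sphere, by voxel-centre inclusion.

    A diameter below the voxel size degenerates to the single voxel nearest
    the centre, so a VOI is never empty.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    center = np.asarray(center, dtype=float)
    x, y, z = grid.center_mesh()
    mask = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= (
        diameter / 2.0
    ) ** 2
    if not mask.any():
        mask[grid.nearest_index(center)] = True
    return mask


def recovery_coefficient(
    volume, mask: np.ndarray, reference_mbq: float, voi_kind: str = "physical"
) -> RecoveryResult:
    """ARC/TARC of a reconstructed volume over a VOI mask."""
    if reference_mbq <= 0:
        raise ValueError("reference activity must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty VOI mask")
    a_e = float(_volume_of(volume)[mask].sum())
    return RecoveryResult(A_E=a_e, A_R=reference_mbq, coefficient=a_e / reference_mbq,
                          voi_kind=voi_kind)


def gaussian_post_filter(volume, sigma_voxels: float = 1.0, kernel_size: int = 7) -> np.ndarray:
    """3-D Gaussian filter with a fixed truncated kernel.

    The kernel is sampled on a kernel_size^3 lattice with the given sigma
    (in voxels) and renormalized to unit sum, so the filter preserves the
    total activity of interior sources.
    """
    if kernel_size % 2 != 1:
        raise ValueError("kernel size must be odd")
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma_voxels**2))
    kernel = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    kernel /= kernel.sum()
    return ndimage.convolve(_volume_of(volume), kernel, mode="constant", cval=0.0)


def _peak_coordinate_mm(volume: np.ndarray, m: float) -> np.ndarray:
    idx = np.unravel_index(int(np.argmax(volume)), volume.shape)
    n = volume.shape[0]
    return (np.asarray(idx, dtype=float) - (n - 1) / 2.0) * m


def plane_distance_analysis(
    reconstructions,
    true_positions,
    voxel_mm: float,
    filter_sigma_voxels: float = 1.0,
    filter_kernel: int = 7,
) -> PlaneDistanceResult:
    """Spatial-integrity analysis of reconstructed point sources on a grid.

    Each volume is Gaussian-filtered, its maximum voxel located and
    converted to millimetres; the positions are grouped into planes by the
    known true coordinates along each axis, per-plane mean coordinates are
    formed, and adjacent-plane distances are reported together with the
    standard deviation of the per-point differences (points paired by
    their lateral true coordinates).
    """
    vols = [_volume_of(v) for v in reconstructions]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError("reconstructed volumes must share one shape")
    truth = np.asarray([np.asarray(p, dtype=float) for p in true_positions])
    if len(vols) != len(truth):
        raise ValueError("need one volume per true source position")

    peaks = np.asarray(
        [
            _peak_coordinate_mm(
                gaussian_post_filter(v, filter_sigma_voxels, filter_kernel), voxel_mm
            )
            for v in vols
        ]
    )

    mean_mm: dict = {}
    std_mm: dict = {}
    for ax_i, ax_name in enumerate(_AXES):
        planes = np.unique(truth[:, ax_i])
        lateral = [i for i in range(3) if i != ax_i]
        means = []
        members = []
        for plane in planes:
            sel = np.where(truth[:, ax_i] == plane)[0]
            # stable lateral ordering so adjacent planes pair point-by-point
            order = np.lexsort((truth[sel, lateral[1]], truth[sel, lateral[0]]))
            sel = sel[order]
            members.append(sel)
            means.append(peaks[sel, ax_i].mean())
        dists = np.diff(np.asarray(means))
        stds = []
        for a, b in zip(members[:-1], members[1:]):
            if len(a) != len(b):
                raise ValueError("planes have mismatched point counts")
            stds.append(float(np.std(peaks[b, ax_i] - peaks[a, ax_i])))
        mean_mm[ax_name] = dists
        std_mm[ax_name] = np.asarray(stds)
    return PlaneDistanceResult(mean_mm=mean_mm, std_mm=std_mm)


def line_profile(image, row_center: int, axis: int = 0, n_rows: int = 7) -> np.ndarray:
    """Mean of ``n_rows`` adjacent rows of a 2-D slice, centred on ``row_center``.

    ``axis`` selects which dimension indexes the rows being averaged; the
    returned profile runs along the other dimension.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice")
    half = n_rows // 2
    lo, hi = row_center - half, row_center + half + 1
    if lo < 0 or hi > img.shape[axis]:
        raise ValueError("profile rows fall outside the slice")
    sl = [slice(None), slice(None)]
    sl[axis] = slice(lo, hi)
    return img[tuple(sl)].mean(axis=axis)


def butterworth_filter(volume, cutoff_cm: float, order: int = 2, voxel_mm: float = 4.0) -> np.ndarray:
    """Radially symmetric 3-D Butterworth low-pass filter.

    Frequency-domain gain 1/sqrt(1 + (f/f_c)^(2 n)) with f the radial
    spatial frequency in cycles/cm and f_c the -3 dB cutoff.  DC gain is 1,
    so the mean (and, for interior sources, the total) is preserved.
    """
    if cutoff_cm <= 0:
        raise ValueError("cutoff must be positive")
    vol = _volume_of(volume)
    n = vol.shape
    freqs = [np.fft.fftfreq(s, d=voxel_mm / 10.0) for s in n]  # cycles/cm
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    f = np.sqrt(fx**2 + fy**2 + fz**2)
    gain = 1.0 / np.sqrt(1.0 + (f / cutoff_cm) ** (2 * order))
    return np.real(np.fft.ifftn(np.fft.fftn(vol) * gain))


def mip(volume, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along one axis."""
    return _volume_of(volume).max(axis=axis)


def dilate_mask(mask: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Binary dilation with a full cubic kernel (odd size)."""
    if kernel_size % 2 != 1:
        raise ValueError("kernel size must be odd")
    structure = np.ones((kernel_size,) * 3, dtype=bool)
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool), structure=structure)
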