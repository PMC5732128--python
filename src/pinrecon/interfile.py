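"""File formats: Interfile-style projection sets and raw volumes.

Projection sets travel as a minimal ASCII ``key := value`` header next to a
little-endian raw binary data file, in the spirit of the Interfile 3.0
exchange convention used in nuclear medicine.  Keys are case-insensitive,
``!`` prefixes and comment lines are tolerated, and unknown keys are
ignored with a logged warning, so headers written by other tools remain
readable.  Volumes (activity in MBq or density in g/cm^3) use raw
little-endian float32 with a small text sidecar; density maps carry their
material labels in a companion uint8 file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import physics
from .mc_forward import ProjectionSet
from .phantoms import ActivityMap, DensityMap, VoxelGrid

__all__ = [
    "InterfileError",
    "write_projections",
    "read_projections",
    "write_volume",
    "read_volume",
]

log = logging.getLogger(__name__)

_PROJ_KEYS = {
    "name of data file",
    "number format",
    "number of bytes per pixel",
    "imagedata byte order",
    "number of projections",
    "matrix size [1]",
    "matrix size [2]",
    "image duration (sec)",
    "energy window lower level (kev)",
    "energy window upper level (kev)",
    "number of histories",
    "interfile",
    "end of interfile",
}


class InterfileError(ValueError):
    """Malformed or inconsistent header/data pair."""


def _parse_header(path: Path) -> dict:
    fields: dict = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if ":=" not in line:
            continue  # tolerated decoration, e.g. '!INTERFILE :=' handled below too
        key, _, value = line.partition(":=")
        key = key.strip().lstrip("!").strip().lower()
        value = value.strip()
        if key and key not in _PROJ_KEYS:
            log.warning("ignoring unknown header key %r", key)
            continue
        fields[key] = value
    return fields


def _require(fields: dict, key: str) -> str:
    if key not in fields or fields[key] == "":
        raise InterfileError(f"missing required header key {key!r}")
    return fields[key]


def write_projections(projections: ProjectionSet, path) -> None:
    """Write a projection set as a text header plus raw float32 binary."""
    path = Path(path)
    data_path = path.with_suffix(".dat")
    k, n1, n2 = projections.counts.shape
    lines = [
        "!INTERFILE :=",
        f"!name of data file := {data_path.name}",
        "!number format := float",
        "!number of bytes per pixel := 4",
        "imagedata byte order := LITTLEENDIAN",
        f"!number of projections := {k}",
        f"!matrix size [1] := {n2}",
        f"!matrix size [2] := {n1}",
        f"image duration (sec) := {projections.acquisition_time!r}",
        f"energy window lower level (kev) := {projections.energy_window[0]!r}",
        f"energy window upper level (kev) := {projections.energy_window[1]!r}",
        f"number of histories := {projections.histories_used}",
        "!END OF INTERFILE :=",
    ]
    path.write_text("\n".join(lines) + "\n")
    projections.counts.astype("<f4").tofile(data_path)


def read_projections(path) -> ProjectionSet:
    """Read a projection set written by :func:`write_projections`.

    Errors name the offending header key; a data file whose size does not
    match the header raises a size-mismatch error.
    """
    path = Path(path)
    fields = _parse_header(path)
    k = int(_require(fields, "number of projections"))
    n2 = int(_require(fields, "matrix size [1]"))
    n1 = int(_require(fields, "matrix size [2]"))
    duration = float(_require(fields, "image duration (sec)"))
    lo = float(_require(fields, "energy window lower level (kev)"))
    hi = float(_require(fields, "energy window upper level (kev)"))
    data_path = path.parent / _require(fields, "name of data file")
    if not data_path.exists():
        raise InterfileError(f"data file {data_path} named by 'name of data file' is missing")
    raw = np.fromfile(data_path, dtype="<f4")
    if raw.size != k * n1 * n2:
        raise InterfileError(
            f"data size mismatch: header promises {k * n1 * n2} values "
            f"('number of projections' x 'matrix size'), file holds {raw.size}"
        )
    return ProjectionSet(
        counts=raw.reshape(k, n1, n2).astype(np.float64),
        acquisition_time=duration,
        energy_window=(lo, hi),
        histories_used=int(fields.get("number of histories", "0") or 0),
    )


def write_volume(volume, path) -> None:
    """Write an activity or density map as raw float32 plus a text sidecar."""
    path = Path(path)
    data_path = path.with_suffix(".raw")
    grid = volume.grid
    if isinstance(volume, DensityMap):
        quantity = "g/cm3"
    elif isinstance(volume, ActivityMap):
        quantity = "MBq"
    else:
        raise TypeError("expected an ActivityMap or DensityMap")
    lines = [
        "pinrecon volume := ",
        f"data file := {data_path.name}",
        f"matrix size := {grid.N}",
        f"voxel size (mm) := {grid.m!r}",
        f"quantity := {quantity}",
        "number format := float",
        "imagedata byte order := LITTLEENDIAN",
    ]
    if isinstance(volume, DensityMap):
        mat_path = path.with_suffix(".mat")
        lines.append(f"material file := {mat_path.name}")
        volume.material.astype(np.uint8).tofile(mat_path)
    path.write_text("\n".join(lines) + "\n")
    volume.values.astype("<f4").tofile(data_path)


def read_volume(path):
    """Read a volume sidecar; returns an ActivityMap or DensityMap by quantity tag."""
    path = Path(path)
    fields: dict = {}
    for raw in path.read_text().splitlines():
        if ":=" not in raw:
            continue
        key, _, value = raw.partition(":=")
        fields[key.strip().lower()] = value.strip()
    n = int(_require(fields, "matrix size"))
    m = float(_require(fields, "voxel size (mm)"))
    quantity = _require(fields, "quantity")
    data_path = path.parent / _require(fields, "data file")
    if not data_path.exists():
        raise InterfileError(f"data file {data_path} is missing")
    raw_vals = np.fromfile(data_path, dtype="<f4")
    if raw_vals.size != n**3:
        raise InterfileError(
            f"data size mismatch: 'matrix size' promises {n**3} voxels, file holds {raw_vals.size}"
        )
    grid = VoxelGrid(n, m)
    values = raw_vals.reshape(grid.shape).astype(np.float64)
    if quantity == "MBq":
        return ActivityMap(grid, values)
    if quantity == "g/cm3":
        material = None
        if "material file" in fields:
            mat_path = path.parent / fields["material file"]
            if mat_path.exists():
                mat = np.fromfile(mat_path, dtype=np.uint8)
                if mat.size != n**3:
                    raise InterfileError("material file size mismatch with 'matrix size'")
                material = mat.reshape(grid.shape)
        if material is None:
            material = np.where(values > 0.05, physics.WATER, physics.AIR).astype(np.uint8)
        return DensityMap(grid, values, material)
    raise InterfileError(f"unknown quantity tag {quantity!r}")
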