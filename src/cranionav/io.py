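"""File I/O: point sets (FCSV / CSV), curves (CSV), transforms, meshes.

Units are mm throughout.  The internal coordinate convention is the CT
mesh frame, interpreted as LPS (the DICOM/CT convention); Slicer FCSV
files declaring a RAS coordinate system are converted on read by negating
x and y.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateInputError, InvalidParameterError, InvalidTransformError
from .mesh import Polyline3D, TriSurface
from .registration import LabeledPointSet
from .transforms import RigidTransform

__all__ = [
    "read_pointset",
    "write_pointset",
    "read_fcsv",
    "write_fcsv",
    "read_points_csv",
    "write_points_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_transform",
    "write_transform",
    "read_mesh",
    "write_mesh",
]

_MESH_EXTENSIONS = {".stl", ".ply"}


# -- point sets ------------------------------------------------------------


def read_fcsv(path: str | Path) -> LabeledPointSet:
    """Read a 3D Slicer markups fiducial file (``.fcsv``).

    Honors the ``# CoordinateSystem`` header: RAS (or the legacy code
    ``0``) is converted to the internal LPS convention by negating x, y.
    """
    path = Path(path)
    coordinate_system = "LPS"
    labels: list[str] = []
    positions: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                value = line.split("=", 1)[1].strip()
                coordinate_system = {"0": "RAS", "1": "LPS"}.get(value, value.upper())
            continue
        fields = line.split(",")
        if len(fields) < 12:
            raise DegenerateInputError(f"malformed fcsv row in {path.name}: {line!r}")
        positions.append([float(fields[1]), float(fields[2]), float(fields[3])])
        labels.append(fields[11])
    if not labels:
        raise DegenerateInputError(f"no fiducials in {path}")
    pos = np.array(positions)
    if coordinate_system == "RAS":
        pos[:, 0] *= -1
        pos[:, 1] *= -1
    elif coordinate_system != "LPS":
        raise InvalidParameterError(f"unsupported CoordinateSystem {coordinate_system!r}")
    return LabeledPointSet(tuple(labels), pos)


def write_fcsv(points: LabeledPointSet, path: str | Path) -> None:
    """Write a Slicer-compatible fcsv file in the internal LPS convention."""
    path = Path(path)
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (label, p) in enumerate(zip(points.labels, points.positions)):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
            f"0,0,0,1,1,1,0,{label},,"
        )
    path.write_text("\n".join(lines) + "\n")


def read_points_csv(path: str | Path) -> LabeledPointSet:
    """Read a plain ``label,x,y,z`` CSV (header optional)."""
    labels, positions = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if fields[0].lower() == "label":
            continue
        if len(fields) != 4:
            raise DegenerateInputError(f"expected label,x,y,z row, got {line!r}")
        labels.append(fields[0])
        positions.append([float(v) for v in fields[1:]])
    if not labels:
        raise DegenerateInputError(f"no points in {path}")
    return LabeledPointSet(tuple(labels), np.array(positions))


def write_points_csv(points: LabeledPointSet, path: str | Path) -> None:
    lines = ["label,x,y,z"]
    for label, p in zip(points.labels, points.positions):
        lines.append(f"{label},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pointset(path: str | Path) -> LabeledPointSet:
    """Dispatch on extension: ``.fcsv`` or ``.csv``."""
    path = Path(path)
    if path.suffix.lower() == ".fcsv":
        return read_fcsv(path)
    if path.suffix.lower() == ".csv":
        return read_points_csv(path)
    raise InvalidParameterError(f"unsupported point-set format {path.suffix!r}")


def write_pointset(points: LabeledPointSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".fcsv":
        write_fcsv(points, path)
    elif path.suffix.lower() == ".csv":
        write_points_csv(points, path)
    else:
        raise InvalidParameterError(f"unsupported point-set format {path.suffix!r}")


# -- curves ----------------------------------------------------------------


def read_curve_csv(path: str | Path) -> Polyline3D:
    """Read one curve: a label header line then ``x,y,z`` rows (mm)."""
    label = ""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                label = line.split(":", 1)[1].strip()
            continue
        fields = [f.strip() for f in line.split(",")]
        if fields[0].lower() == "x":
            continue
        if len(fields) != 3:
            raise DegenerateInputError(f"expected x,y,z row, got {line!r}")
        rows.append([float(v) for v in fields])
    return Polyline3D(np.array(rows), label=label)


def write_curve_csv(curve: Polyline3D, path: str | Path) -> None:
    lines = [f"# curve: {curve.label}", "x,y,z"]
    for p in curve.points:
        lines.append(f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- rigid transforms ------------------------------------------------------


def read_transform(path: str | Path) -> tuple[str, str, RigidTransform]:
    """Read ``(from_frame, to_frame, transform)`` from a JSON transform file.

    The file holds the frame names and the 4x4 row-major homogeneous
    matrix in mm; orthonormality is validated on load.
    """
    data = json.loads(Path(path).read_text())
    for key in ("from", "to", "matrix"):
        if key not in data:
            raise InvalidTransformError(f"transform file missing {key!r} field")
    matrix = np.asarray(data["matrix"], dtype=float)
    return str(data["from"]), str(data["to"]), RigidTransform.from_matrix(matrix)


def write_transform(
    from_frame: str, to_frame: str, transform: RigidTransform, path: str | Path
) -> None:
    payload = {
        "from": from_frame,
        "to": to_frame,
        "units": "mm",
        "matrix": [[float(v) for v in row] for row in transform.matrix],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# -- meshes ----------------------------------------------------------------


def read_mesh(path: str | Path) -> TriSurface:
    """Read an STL (binary or ASCII) or PLY mesh, units mm.

    The mesh is validated against the surface invariants (finite
    coordinates, valid indices, no degenerate triangles).
    """
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise InvalidParameterError(f"unsupported mesh format {path.suffix!r}")
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return TriSurface.from_trimesh(mesh)


def write_mesh(surface: TriSurface, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise InvalidParameterError(f"unsupported mesh format {path.suffix!r}")
    surface.to_trimesh().export(str(path))
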