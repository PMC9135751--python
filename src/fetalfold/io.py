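"""Mesh and table serialization helpers.

Surfaces are written as binary little-endian PLY with per-vertex integer
``region`` and ``hemisphere`` properties (plus optional float properties for
computed features); OBJ export carries geometry only.  Tables are RFC-4180
CSV with a leading ``#`` comment line carrying provenance.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from trimesh.exchange import ply as _ply

from .errors import ValidationError
from .surface import SurfaceMesh

_PLY_DTYPES = {
    "float": "<f4",
    "double": "<f8",
    "int": "<i4",
    "uint": "<u4",
    "short": "<i2",
    "ushort": "<u2",
    "uchar": "<u1",
    "char": "<i1",
}


def write_surface_ply(
    mesh: SurfaceMesh,
    path: str | Path,
    extra_vertex_properties: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a surface as binary PLY with region/hemisphere vertex properties."""
    m = mesh.mesh.copy()
    m.vertex_attributes["region"] = mesh.region.astype(np.int32)
    m.vertex_attributes["hemisphere"] = mesh.hemisphere.astype(np.int32)
    for name, values in (extra_vertex_properties or {}).items():
        values = np.asarray(values)
        if len(values) != len(mesh.vertices):
            raise ValidationError(f"property {name!r} length mismatch")
        m.vertex_attributes[name] = values.astype(np.float32)
    data = _ply.export_ply(m, encoding="binary_little_endian", include_attributes=True)
    Path(path).write_bytes(data)


def write_surface_obj(mesh: SurfaceMesh, path: str | Path) -> None:
    """Geometry-only OBJ export (regions are not representable in OBJ)."""
    Path(path).write_text(mesh.mesh.export(file_type="obj"))


def read_ply_vertex_properties(path: str | Path) -> dict[str, np.ndarray]:
    """Read all per-vertex properties from a binary little-endian PLY file.

    Returns a mapping including ``x``/``y``/``z`` and any custom properties
    (trimesh's own loader discards non-standard vertex attributes).
    """
    raw = Path(path).read_bytes()
    header_end = raw.index(b"end_header\n") + len(b"end_header\n")
    header = raw[:header_end].decode("ascii").splitlines()
    if "format binary_little_endian 1.0" not in header:
        raise ValidationError(f"{path}: not a binary little-endian PLY")
    n_vertex = None
    fields: list[tuple[str, str]] = []
    in_vertex = False
    for line in header:
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vertex = int(parts[2])
            in_vertex = True
        elif parts[0] == "element":
            in_vertex = False
        elif in_vertex and parts[0] == "property":
            if parts[1] == "list":
                raise ValidationError("list property in vertex element")
            fields.append((parts[2], _PLY_DTYPES[parts[1]]))
    if n_vertex is None:
        raise ValidationError(f"{path}: no vertex element")
    dtype = np.dtype(fields)
    arr = np.frombuffer(raw, dtype=dtype, count=n_vertex, offset=header_end)
    return {name: np.array(arr[name]) for name, _ in fields}


def load_surface_ply(path: str | Path) -> SurfaceMesh:
    """Load a surface written by :func:`write_surface_ply`."""
    m = trimesh.load(
        _io.BytesIO(Path(path).read_bytes()), file_type="ply", process=False
    )
    props = read_ply_vertex_properties(path)
    if "region" not in props or "hemisphere" not in props:
        raise ValidationError(f"{path}: missing region/hemisphere properties")
    return SurfaceMesh(
        mesh=m,
        hemisphere=props["hemisphere"].astype(np.int8),
        region=props["region"].astype(np.int32),
    )


def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    """RFC-4180 CSV with an optional leading provenance comment."""
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
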