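"""Triangle-mesh containers, file I/O and geometric queries.

Shapes are triangle surface meshes in millimetre world coordinates.  The
varifold representation used downstream is orientation-free, so triangle
winding is preserved on read/write but never validated or relied upon.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "SubjectRecord",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "triangle_centres_and_tangents",
    "mirror_mesh",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: triangles with area below this floor (mm^2) are dropped during validation
DEFAULT_AREA_FLOOR = 1e-12


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed."""


class MeshValidationError(ValueError):
    """Raised when a mesh violates the TriMesh invariants."""


@dataclass
class TriMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) in mm, ``triangles`` (m, 3) 0-based."""

    vertices: np.ndarray
    triangles: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    # ------------------------------------------------------------------ api
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    def validated(self, area_floor: float = DEFAULT_AREA_FLOOR) -> "TriMesh":
        """Return a copy satisfying all invariants.

        Raises
        ------
        MeshValidationError
            On out-of-range indices, repeated indices within a triangle, or
            if no triangle survives the degeneracy floor.
        """
        v, t = self.vertices, self.triangles
        if not np.isfinite(v).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise MeshValidationError(
                f"triangle index out of range [0, {len(v)}): "
                f"min={t.min() if t.size else None} max={t.max() if t.size else None}"
            )
        if t.size:
            rep = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
            if rep.any():
                raise MeshValidationError(
                    f"{int(rep.sum())} triangle(s) with a repeated vertex index"
                )
        areas = _areas(v, t)
        keep = areas > area_floor
        if not keep.any():
            raise MeshValidationError("mesh has no triangle above the area floor")
        if keep.all():
            return replace(self)
        return TriMesh(v.copy(), t[keep], name=self.name)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def diameter(self) -> float:
        lo, hi = self.bounds()
        return float(np.linalg.norm(hi - lo))

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.triangles.copy(), name=self.name)


def _areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    if triangles.size == 0:
        return np.zeros(0)
    p0, p1, p2 = (vertices[triangles[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


@dataclass
class SubjectRecord:
    """One cohort entry: bilateral meshes plus time label and covariates.

    ``eyo`` is the estimated years to expected symptom onset (age minus mean
    familial onset age); negative values are presymptomatic.
    """

    subject_id: str
    left_mesh: TriMesh
    right_mesh: TriMesh
    eyo: float
    group: str
    sex: str
    site: str
    family_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.eyo):
            raise ValueError(f"{self.subject_id}: non-finite eyo")
        for attr in ("group", "sex", "site", "family_id"):
            if not str(getattr(self, attr)):
                raise ValueError(f"{self.subject_id}: empty {attr}")


# --------------------------------------------------------------------- I/O

_EXT_FORMAT = {".ply": "ply", ".vtk": "vtk", ".off": "off"}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise MeshFormatError(f"cannot infer mesh format from suffix {path.suffix!r}")


def read_mesh(path: str | os.PathLike, fmt: str = "auto") -> TriMesh:
    """Read a triangle mesh from PLY (ascii or binary), legacy VTK, or OFF.

    Quad faces are split along the 0-2 diagonal.  The returned mesh is
    validated (degenerate triangles dropped).
    """
    path = Path(path)
    if not path.is_file():
        raise MeshFormatError(f"no such file: {path}")
    fmt = _resolve_format(path, fmt)
    if fmt == "vtk":
        mesh = _read_vtk_polydata(path)
    elif fmt in ("ply", "off"):
        try:
            tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:  # trimesh raises many types on bad input
            raise MeshFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
        if not hasattr(tm, "faces") or len(tm.faces) == 0:
            raise MeshFormatError(f"{path}: no faces found")
        mesh = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name=path.stem)
    else:
        raise MeshFormatError(f"unknown format {fmt!r}")
    return mesh.validated()


def write_mesh(mesh: TriMesh, path: str | os.PathLike, fmt: str = "auto") -> None:
    """Write a mesh as ascii PLY, legacy VTK POLYDATA, or OFF."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "vtk":
        _write_vtk_polydata(mesh, path)
        return
    tm = _trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif fmt == "off":
        data = tm.export(file_type="off")
    else:
        raise MeshFormatError(f"unknown format {fmt!r}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def _split_polys(counts_and_indices: list[int]) -> np.ndarray:
    """Fan-triangulate a legacy-VTK POLYGONS block (quads split 0-2)."""
    tris: list[list[int]] = []
    i = 0
    data = counts_and_indices
    while i < len(data):
        n = data[i]
        poly = data[i + 1 : i + 1 + n]
        for k in range(1, n - 1):
            tris.append([poly[0], poly[k], poly[k + 1]])
        i += 1 + n
    return np.asarray(tris, dtype=np.int64)


def _read_vtk_polydata(path: Path) -> TriMesh:
    try:
        with open(path) as fh:
            tokens_iter = (tok for line in fh for tok in line.split())
            tokens = list(tokens_iter)
        upper = [t.upper() for t in tokens]
        ip = upper.index("POINTS")
        n_pts = int(tokens[ip + 1])
        coords = np.asarray(tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=np.float64)
        vertices = coords.reshape(n_pts, 3)
        ipoly = upper.index("POLYGONS")
        n_poly = int(tokens[ipoly + 1])
        n_ints = int(tokens[ipoly + 2])
        body = [int(t) for t in tokens[ipoly + 3 : ipoly + 3 + n_ints]]
        triangles = _split_polys(body)
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"failed to parse {path} as legacy VTK: {exc}") from exc
    if len(triangles) == 0:
        raise MeshFormatError(f"{path}: no polygons found")
    return TriMesh(vertices, triangles, name=path.stem)


def _write_vtk_polydata(mesh: TriMesh, path: Path) -> None:
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"{mesh.name or 'mesh'}\nASCII\nDATASET POLYDATA\n")
    buf.write(f"POINTS {mesh.n_vertices} double\n")
    np.savetxt(buf, mesh.vertices, fmt="%.9g")
    m = mesh.n_triangles
    buf.write(f"POLYGONS {m} {4 * m}\n")
    block = np.column_stack([np.full(m, 3, dtype=np.int64), mesh.triangles])
    np.savetxt(buf, block, fmt="%d")
    Path(path).write_text(buf.getvalue())


# ----------------------------------------------------------------- geometry

def triangle_centres_and_tangents(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle centre and area-weighted normal.

    Returns ``(centres, tangents)`` each of shape (m, 3); ``tangents[k]`` is
    0.5 * (v1 - v0) x (v2 - v0), whose norm is the triangle area.
    """
    p0 = mesh.vertices[mesh.triangles[:, 0]]
    p1 = mesh.vertices[mesh.triangles[:, 1]]
    p2 = mesh.vertices[mesh.triangles[:, 2]]
    centres = (p0 + p1 + p2) / 3.0
    tangents = 0.5 * np.cross(p1 - p0, p2 - p0)
    return centres, tangents


def mirror_mesh(mesh: TriMesh, plane_x: float = 0.0) -> TriMesh:
    """Reflect a mesh across the sagittal plane ``x = plane_x``.

    Winding is left untouched: downstream varifold metrics are orientation
    free, so re-winding after reflection is unnecessary.
    """
    if not np.isfinite(plane_x):
        raise ValueError("mirror plane offset must be finite")
    v = mesh.vertices.copy()
    v[:, 0] = 2.0 * plane_x - v[:, 0]
    return TriMesh(v, mesh.triangles.copy(), name=mesh.name)


# ------------------------------------------------------------- cohort table

COHORT_COLUMNS = [
    "subject_id",
    "left_mesh",
    "right_mesh",
    "eyo",
    "group",
    "sex",
    "site",
    "family_id",
]


def read_cohort_csv(path: str | os.PathLike, load_meshes: bool = True) -> list[SubjectRecord] | pd.DataFrame:
    """Load a cohort table; mesh path columns are resolved relative to the CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str, "site": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    if not load_meshes:
        return df
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                left_mesh=read_mesh(base / str(row.left_mesh)),
                right_mesh=read_mesh(base / str(row.right_mesh)),
                eyo=float(row.eyo),
                group=str(row.group),
                sex=str(row.sex),
                site=str(row.site),
                family_id=str(row.family_id),
            )
        )
    return records


def write_cohort_csv(rows: Iterable[dict], path: str | os.PathLike) -> None:
    df = pd.DataFrame(list(rows), columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)
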