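"""Triangle-mesh primitives for joint-space morphometry.

All geometry is expressed in millimetres in a right-handed frame with +z
pointing proximally along the tibial shaft, +y anterior and +x lateral.
The workhorse query is the intersection of a *vertical* line (parallel to
z) with a triangle surface: joint-space heights, implant fitting checks and
deviation maps are all measured along that direction.

STL and PLY input/output is delegated to :mod:`trimesh`; the vertical-line
intersector is implemented here directly (vectorised over query points) so
that batches of 10^4 lines remain fast on a single CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

logger = logging.getLogger("talofit")

#: Two hits closer than this (mm) along one line are merged: a line crossing
#: a shared edge or vertex of a conforming mesh is counted once.
MERGE_TOL = 1e-9

#: Triangles with xy-projected area below this (mm^2) cannot be crossed
#: transversally by a vertical line and are skipped.
_PROJ_AREA_TOL = 1e-12


@dataclass(frozen=True)
class TriMesh:
    """An immutable triangle surface mesh in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if f.shape[0] < 1:
            raise ValueError("mesh must have at least one face")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise ValueError("face indices out of range")
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValueError("every face must reference three distinct vertices")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- basic queries ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) corner coordinates."""
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def volume(self) -> float:
        return float(self.to_trimesh().volume)

    # -- rigid motions ----------------------------------------------------

    def translated(self, offset) -> "TriMesh":
        off = np.asarray(offset, dtype=float).reshape(3)
        return TriMesh(self.vertices + off, self.faces, self.name)

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        """Apply ``v -> R v + t`` to every vertex."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = np.asarray(translation, dtype=float).reshape(3)
        return TriMesh(self.vertices @ R.T + t, self.faces, self.name)

    def mirrored_x(self) -> "TriMesh":
        """Mirror about the sagittal (x = 0) plane, preserving orientation."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return TriMesh(v, self.faces[:, ::-1], self.name)

    # -- interop ----------------------------------------------------------

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh, name: str = "") -> "TriMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), name)


def load_mesh(path, name: str | None = None) -> TriMesh:
    """Read an STL (binary or ASCII) or PLY file; units are assumed mm."""
    path = Path(path)
    tm = _trimesh.load_mesh(str(path), process=False)
    if isinstance(tm, _trimesh.Scene):
        tm = tm.to_mesh()
    return TriMesh.from_trimesh(tm, name if name is not None else path.stem)


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as STL or PLY according to the file extension."""
    mesh.to_trimesh().export(str(path))


@dataclass(frozen=True)
class GridPoint:
    """One node of the standard 3x3 measurement grid.

    ``x`` is medio-lateral, ``y`` antero-posterior (mm); ``index`` is the
    H label (1-9).  Standard nodes sit at offsets of -12, 0 or +12 mm from
    the joint centre in each direction.
    """

    x: float
    y: float
    index: int

    STANDARD_OFFSETS = (-12.0, 0.0, 12.0)

    def __post_init__(self) -> None:
        if not (1 <= int(self.index) <= 9):
            raise ValueError("grid index must be 1-9")


@dataclass(frozen=True)
class VerticalHits:
    """Sorted intersection heights of one vertical line with a mesh."""

    z_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float).reshape(-1)
        if np.any(np.diff(z) < 0):
            raise ValueError("z_values must be sorted ascending")
        object.__setattr__(self, "z_values", z)

    def __len__(self) -> int:
        return len(self.z_values)

    @property
    def is_miss(self) -> bool:
        return len(self.z_values) == 0

    @property
    def lowest(self) -> float:
        return float(self.z_values[0])

    @property
    def highest(self) -> float:
        return float(self.z_values[-1])


def _merge_close(z: np.ndarray, tol: float = MERGE_TOL) -> np.ndarray:
    """Collapse sorted values closer than ``tol`` (shared-edge tie rule)."""
    if len(z) < 2:
        return z
    keep = np.empty(len(z), dtype=bool)
    keep[0] = True
    keep[1:] = np.diff(z) > tol
    return z[keep]


def vertical_intersections_batch(mesh: TriMesh, xy) -> list[np.ndarray]:
    """Intersect many vertical lines with a mesh.

    Parameters
    ----------
    mesh : TriMesh
    xy : (q, 2) array of line positions in the mesh's own frame

    Returns
    -------
    list of q sorted arrays of intersection heights (mm); an empty array
    signals a miss.  Hits on shared edges/vertices are merged within
    ``MERGE_TOL``; degenerate (zero xy-area) triangles are skipped with a
    logged warning.
    """
    pts = np.asarray(xy, dtype=float).reshape(-1, 2)
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = b - a
    e2 = c - a
    # signed xy-projected area x2; vertical or degenerate triangles drop out
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    ok = np.abs(det) > _PROJ_AREA_TOL
    n_skipped = int(np.count_nonzero(~ok))
    if n_skipped:
        area3d = 0.5 * np.linalg.norm(np.cross(e1[~ok], e2[~ok]), axis=1)
        n_degen = int(np.count_nonzero(area3d < 1e-9))
        if n_degen:
            logger.warning(
                "skipping %d degenerate (zero-area) triangle(s) in %r",
                n_degen,
                mesh.name,
            )
    a, e1, e2, det = a[ok], e1[ok], e2[ok], det[ok]
    if len(det) == 0:
        return [np.empty(0) for _ in range(len(pts))]

    # Pre-computed barycentric solve: for p = (x, y),
    #   u = ((p-a) x e2) / (e1 x e2),  v = (e1 x (p-a)) / (e1 x e2)   (2D crosses)
    inv_det = 1.0 / det
    results: list[np.ndarray] = []
    tol = 1e-10
    chunk = max(1, int(2.5e6 // max(len(det), 1)))
    for start in range(0, len(pts), chunk):
        p = pts[start : start + chunk]  # (q, 2)
        dx = p[:, None, 0] - a[None, :, 0]
        dy = p[:, None, 1] - a[None, :, 1]
        u = (dx * e2[None, :, 1] - dy * e2[None, :, 0]) * inv_det[None, :]
        v = (e1[None, :, 0] * dy - e1[None, :, 1] * dx) * inv_det[None, :]
        inside = (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
        z = a[None, :, 2] + u * e1[None, :, 2] + v * e2[None, :, 2]
        for row_inside, row_z in zip(inside, z):
            hits = np.sort(row_z[row_inside])
            results.append(_merge_close(hits))
    return results


def vertical_intersections(mesh: TriMesh, x: float, y: float) -> VerticalHits:
    """All heights z where the vertical line through (x, y) crosses ``mesh``."""
    (z,) = vertical_intersections_batch(mesh, [(x, y)])
    return VerticalHits(z)


def grid_solid(X, Y, z_bottom, z_top, name: str = "") -> TriMesh:
    """Watertight solid between two height fields over a structured grid.

    ``X``/``Y`` are (m, k) arrays of planform coordinates (rows advance in
    +y, columns in +x); ``z_bottom``/``z_top`` are matching height arrays
    (scalars are broadcast).  The top and bottom sheets are triangulated,
    and side walls stitch their shared boundary loop, yielding a closed,
    consistently outward-oriented surface.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("X and Y must be matching 2-D grids of size >= 2x2")
    m, k = X.shape
    zb = np.broadcast_to(np.asarray(z_bottom, dtype=float), (m, k))
    zt = np.broadcast_to(np.asarray(z_top, dtype=float), (m, k))

    bottom = np.column_stack([X.ravel(), Y.ravel(), zb.ravel()])
    top = np.column_stack([X.ravel(), Y.ravel(), zt.ravel()])
    vertices = np.vstack([bottom, top])
    nv = m * k

    idx = np.arange(nv).reshape(m, k)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[:-1, 1:].ravel()
    v01 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    # top sheet: counter-clockwise seen from +z (outward up)
    top_faces = np.vstack(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    ) + nv
    # bottom sheet: reversed winding (outward down)
    bot_faces = np.vstack(
        [np.column_stack([v00, v11, v10]), np.column_stack([v00, v01, v11])]
    )

    # boundary loop, counter-clockwise in the plane
    loop = np.concatenate(
        [idx[0, :-1], idx[:-1, -1], idx[-1, :0:-1], idx[::-1, 0][:-1]]
    )
    nxt = np.roll(loop, -1)
    walls = np.vstack(
        [
            np.column_stack([loop, nxt, nxt + nv]),
            np.column_stack([loop, nxt + nv, loop + nv]),
        ]
    )
    return TriMesh(vertices, np.vstack([bot_faces, top_faces, walls]), name)


def signed_vertical_gap(z_upper: float, z_lower: float) -> float:
    """Signed vertical clearance: positive = gap, negative = overlap."""
    z_upper = float(z_upper)
    z_lower = float(z_lower)
    if not (np.isfinite(z_upper) and np.isfinite(z_lower)):
        raise ValueError("gap endpoints must be finite")
    return z_upper - z_lower
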