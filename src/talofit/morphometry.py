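"""Joint frame construction and the nine-point joint-space measurement.

The tibiotalar joint space is characterised by nine vertical clearances
H1-H9 sampled on a 3x3 grid: a central point plus offsets of +/-12 mm in
the antero-posterior and medio-lateral directions (the intersections of six
orthogonal section planes with the joint).  By convention H1/H2/H3 form the
anterior row, H7/H8/H9 the posterior row, H1/H4/H7 the lateral column and
H3/H6/H9 the medial column; H5 is central.

Measurement happens in a *joint frame* emulating a standing posture: the
tibial shaft is vertical (+z proximal) and the plantar landmarks define the
antero-posterior axis.  Meshes exported pre-aligned to that frame can be
measured with the identity frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridPoint, TriMesh, vertical_intersections_batch

logger = logging.getLogger("talofit")

GRID_SPACING = 12.0  # mm between neighbouring grid nodes

#: H label -> (x, y) node position in the joint frame (mm).
#: Rows run anterior (y=+12) to posterior (y=-12); columns lateral (x=-12)
#: to medial (x=+12).
NODE_XY: dict[int, tuple[float, float]] = {
    1: (-12.0, 12.0),
    2: (0.0, 12.0),
    3: (12.0, 12.0),
    4: (-12.0, 0.0),
    5: (0.0, 0.0),
    6: (12.0, 0.0),
    7: (-12.0, -12.0),
    8: (0.0, -12.0),
    9: (12.0, -12.0),
}


class AlignmentError(ValueError):
    """Raised when landmarks cannot define an orthonormal joint frame."""


class MeasurementError(RuntimeError):
    """Raised when a grid line misses one of the articular surfaces."""


@dataclass(frozen=True)
class MeasurementGrid:
    """The ordered 3x3 grid of measurement nodes."""

    spacing: float = GRID_SPACING

    def node(self, index: int) -> GridPoint:
        x, y = NODE_XY[index]
        s = self.spacing / GRID_SPACING
        return GridPoint(x * s, y * s, index)

    @property
    def nodes(self) -> list[GridPoint]:
        return [self.node(j) for j in range(1, 10)]

    def node_xy(self) -> np.ndarray:
        """(9, 2) node coordinates in H-label order."""
        return np.array([(p.x, p.y) for p in self.nodes])


def default_grid() -> MeasurementGrid:
    return MeasurementGrid()


@dataclass(frozen=True)
class JointFrame:
    """Right-handed orthonormal joint frame (x lateral, y anterior, z proximal)."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        axes = [np.asarray(a, dtype=float).reshape(3) for a in (self.axis_x, self.axis_y, self.axis_z)]
        R = np.stack(axes, axis=1)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise AlignmentError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise AlignmentError("frame must be right-handed")
        object.__setattr__(self, "origin", o)
        for name, a in zip(("axis_x", "axis_y", "axis_z"), axes):
            object.__setattr__(self, name, a)

    @classmethod
    def identity(cls, origin=(0.0, 0.0, 0.0)) -> "JointFrame":
        return cls(np.asarray(origin, float), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix (columns are the axes)."""
        return np.stack([self.axis_x, self.axis_y, self.axis_z], axis=1)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.rotation

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "JointFrame":
        """The same anatomical frame after a rigid motion of the scene."""
        R = np.asarray(rotation, float).reshape(3, 3)
        t = np.asarray(translation, float).reshape(3)
        return JointFrame(
            R @ self.origin + t, R @ self.axis_x, R @ self.axis_y, R @ self.axis_z
        )


@dataclass(frozen=True)
class JointSpaceProfile:
    """One case's nine joint-space heights H1-H9 (mm)."""

    case_id: str
    H: np.ndarray
    side: str = "right"
    sex: str | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.H, dtype=float).reshape(-1)
        if h.shape != (9,):
            raise ValueError("a profile holds exactly nine heights")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if np.any(h < 0):
            logger.warning(
                "profile %s contains negative joint-space heights (interpenetration)",
                self.case_id,
            )
        if self.side not in ("left", "right", ""):
            raise ValueError("side must be 'left', 'right' or empty")
        object.__setattr__(self, "H", h)

    def __getitem__(self, index: int) -> float:
        """H value by its 1-based label."""
        return float(self.H[index - 1])


def distal_articular_centroid(tibia: TriMesh) -> np.ndarray:
    """Centroid of the tibia's distal articular region.

    The articular (plafond) surface is taken as the set of downward-facing
    triangles; the centroid is area-weighted.  Falls back to the lowest 10%
    band of vertices for meshes without downward faces (open sheets seen
    from below).
    """
    tri = tibia.vertices[tibia.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(normals, axis=1)
    nz = np.divide(normals[:, 2], 2.0 * areas, out=np.zeros(len(areas)), where=areas > 0)
    down = (nz < -0.5) & (areas > 0)
    if down.any():
        centroids = tri[down].mean(axis=1)
        w = areas[down]
        return (centroids * w[:, None]).sum(axis=0) / w.sum()
    z = tibia.vertices[:, 2]
    band = max(0.1 * (z.max() - z.min()), 1.0)
    return tibia.vertices[z <= z.min() + band].mean(axis=0)


def build_joint_frame(tibia: TriMesh, landmarks: dict | None = None) -> JointFrame:
    """Establish the joint frame from anatomical landmarks.

    ``landmarks`` maps names to 3D points and must contain ``shaft_distal``
    and ``shaft_proximal`` (tibial axis) plus ``mt5_head`` and
    ``calcaneal_tuberosity`` (the plantar line whose 90-degree relation to
    the shaft emulates standing).  An optional ``articular_center`` fixes
    the origin; otherwise the distal articular centroid of the tibia is
    used.  Without landmarks the mesh is assumed pre-aligned and the
    identity frame is returned.
    """
    if landmarks is None:
        return JointFrame.identity(distal_articular_centroid(tibia))

    required = ("shaft_distal", "shaft_proximal", "mt5_head", "calcaneal_tuberosity")
    missing = [k for k in required if k not in landmarks]
    if missing:
        raise AlignmentError(f"missing landmarks: {missing}")
    pts = {k: np.asarray(landmarks[k], dtype=float).reshape(3) for k in landmarks}

    shaft = pts["shaft_proximal"] - pts["shaft_distal"]
    norm = np.linalg.norm(shaft)
    if norm < 1e-9:
        raise AlignmentError("tibial shaft landmarks coincide")
    axis_z = shaft / norm

    foot = pts["mt5_head"] - pts["calcaneal_tuberosity"]
    foot_inplane = foot - np.dot(foot, axis_z) * axis_z
    norm = np.linalg.norm(foot_inplane)
    if norm < 1e-9:
        raise AlignmentError("foot landmarks collinear with the tibial shaft")
    axis_y = foot_inplane / norm
    axis_x = np.cross(axis_y, axis_z)

    origin = pts.get("articular_center")
    if origin is None:
        origin = distal_articular_centroid(tibia)
    return JointFrame(origin, axis_x, axis_y, axis_z)


def measure_joint_space(
    tibia: TriMesh,
    talus: TriMesh,
    frame: JointFrame | None = None,
    grid: MeasurementGrid | None = None,
    case_id: str = "",
    side: str = "right",
    sex: str | None = None,
) -> JointSpaceProfile:
    """Measure H1-H9 between a tibia and a talus.

    At each grid node the articulating surfaces are the *lowest* tibial and
    the *highest* talar crossing of the vertical line through the node, and
    H is their signed vertical gap.  Left-sided joints are mirrored about
    the sagittal plane first, so lateral/medial columns pool consistently
    across sides.  A node whose line misses either bone raises
    :class:`MeasurementError` naming the node; a negative H is retained
    with a logged warning.
    """
    frame = frame or JointFrame.identity()
    grid = grid or default_grid()

    tib_local = TriMesh(frame.to_local(tibia.vertices), tibia.faces, tibia.name)
    tal_local = TriMesh(frame.to_local(talus.vertices), talus.faces, talus.name)
    if side == "left":
        tib_local = tib_local.mirrored_x()
        tal_local = tal_local.mirrored_x()

    xy = grid.node_xy()
    tib_hits = vertical_intersections_batch(tib_local, xy)
    tal_hits = vertical_intersections_batch(tal_local, xy)

    heights = np.empty(9)
    for j, (th, ah) in enumerate(zip(tib_hits, tal_hits), start=1):
        if len(th) == 0:
            raise MeasurementError(f"grid line H{j} misses the tibia")
        if len(ah) == 0:
            raise MeasurementError(f"grid line H{j} misses the talus")
        heights[j - 1] = th[0] - ah[-1]
        if heights[j - 1] < 0:
            logger.warning("H%d is negative (%.3f mm): bones interpenetrate", j, heights[j - 1])
    return JointSpaceProfile(case_id=case_id, H=heights, side=side, sex=sex)
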