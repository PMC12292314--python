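"""Standardized fusion-implant construction.

The implant is a 24 x 24 mm block whose superior surface interpolates the
nine cohort-mean joint-space heights, so that it fills the (debrided) joint
space with an anatomically conforming cap.  The four vertical edges of the
footprint are rounded with a 5 mm fillet, and two fixation screw axes are
recorded as metadata: one directed proximally into the tibia at 35 degrees
to the horizontal plane and one distally into the talus at 30 degrees.

The superior surface is the biquadratic tensor-product Lagrange polynomial
through the 3x3 nodal grid -- the unique minimal-degree surface that
reproduces all nine nodal heights.  The inferior face of the exported block
is flat; fit evaluation against a talar bed uses the cylindrical seat
template carried in :attr:`ImplantSpec.seat_radius` (see the deviation
module).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box as _box

from .cohort import CohortSummary
from .geometry import TriMesh, grid_solid
from .morphometry import GRID_SPACING

FOOTPRINT_SIDE = 24.0  # mm
FILLET_RADIUS = 5.0  # mm


class DomainError(ValueError):
    """Raised when the height field is queried outside the footprint."""


class MeshingError(ValueError):
    """Raised for mesh resolutions too coarse to resolve the geometry."""


def lagrange_weights(t, spacing: float = GRID_SPACING) -> np.ndarray:
    """Quadratic Lagrange basis at nodes (-spacing, 0, +spacing).

    Returns weights stacked on the last axis, ordered (-s, 0, +s).
    """
    t = np.asarray(t, dtype=float)
    s = float(spacing)
    return np.stack(
        [
            t * (t - s) / (2.0 * s * s),
            (s - t) * (s + t) / (s * s),
            t * (t + s) / (2.0 * s * s),
        ],
        axis=-1,
    )


def biquadratic_surface(nodal_heights, x, y, spacing: float = GRID_SPACING):
    """Evaluate the biquadratic interpolant of a 3x3 nodal grid.

    ``nodal_heights`` is ordered H1..H9 (anterior row first, lateral column
    first; see :data:`talofit.morphometry.NODE_XY`).  No domain clipping is
    performed, so the polynomial extrapolates naturally outside the grid.
    """
    N = np.asarray(nodal_heights, dtype=float).reshape(3, 3)
    wx = lagrange_weights(x, spacing)  # ordered x = -s, 0, +s  (columns)
    wy = lagrange_weights(y, spacing)  # ordered y = -s, 0, +s
    # rows of N run anterior (y=+s) to posterior (y=-s): flip the y weights
    wy = wy[..., ::-1]
    return np.einsum("...r,rc,...c->...", wy, N, wx)


@dataclass(frozen=True)
class ImplantSpec:
    """Parametric definition of the standardized fusion implant."""

    nodal_heights: np.ndarray
    footprint: float = FOOTPRINT_SIDE
    fillet_radius: float = FILLET_RADIUS
    screw_angle_tibial: float = 35.0  # degrees to the horizontal plane
    screw_angle_talar: float = 30.0
    screw_diameter: float = 4.0
    mesh_resolution: float = 0.5  # mm
    seat_radius: float = 21.0  # sagittal radius of the talar bed template

    def __post_init__(self) -> None:
        h = np.asarray(self.nodal_heights, dtype=float).reshape(-1)
        if h.shape != (9,):
            raise ValueError("the implant needs exactly nine nodal heights")
        if np.any(h <= 0):
            raise ValueError("nodal heights must be positive")
        if not (0.0 <= self.fillet_radius < self.footprint / 2):
            raise ValueError("fillet radius must lie in [0, footprint/2)")
        for ang in (self.screw_angle_tibial, self.screw_angle_talar):
            if not (0.0 < ang < 90.0):
                raise ValueError("screw angles must lie in (0, 90) degrees")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh resolution must be positive")
        object.__setattr__(self, "nodal_heights", h)

    @classmethod
    def from_summary(cls, summary: CohortSummary, **kwargs) -> "ImplantSpec":
        """Spec whose nodal heights are the cohort means."""
        return cls(nodal_heights=summary.H_ave.copy(), **kwargs)

    @property
    def half(self) -> float:
        return self.footprint / 2.0

    def height_field(self, x, y):
        """Superior-surface height (mm) at footprint coordinates (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        tol = 1e-9
        if np.any(np.abs(x) > self.half + tol) or np.any(np.abs(y) > self.half + tol):
            raise DomainError("height field queried outside the 24 x 24 mm footprint")
        return biquadratic_surface(self.nodal_heights, x, y)

    def footprint_outline(self, quad_segs: int = 64):
        """Shapely polygon of the rounded-square footprint."""
        if self.fillet_radius <= 0:
            return _box(-self.half, -self.half, self.half, self.half)
        inner = self.half - self.fillet_radius
        return _box(-inner, -inner, inner, inner).buffer(
            self.fillet_radius, quad_segs=quad_segs, join_style="round"
        )

    def to_json(self, path, screw_axes=None) -> None:
        d = {
            "footprint_mm": self.footprint,
            "nodal_heights_mm": self.nodal_heights.tolist(),
            "fillet_radius_mm": self.fillet_radius,
            "screw_angle_tibial_deg": self.screw_angle_tibial,
            "screw_angle_talar_deg": self.screw_angle_talar,
            "screw_diameter_mm": self.screw_diameter,
            "mesh_resolution_mm": self.mesh_resolution,
            "seat_radius_mm": self.seat_radius,
        }
        if screw_axes is not None:
            d["screw_axes"] = [
                {"origin": list(map(float, o)), "direction": list(map(float, v))}
                for o, v in screw_axes
            ]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def rounded_square_area(side: float = FOOTPRINT_SIDE, r: float = FILLET_RADIUS) -> float:
    """Closed-form area of a square with circularly rounded corners."""
    return side * side - (4.0 - np.pi) * r * r


def _rounded_square_grid(half: float, r: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Structured grid filling the rounded square.

    A regular m x m grid on the square is remapped in each corner zone by
    the radial Chebyshev map (square of side r -> quarter disc of radius r),
    which carries the square boundary onto the filleted outline while
    keeping the grid topology intact.
    """
    s = np.linspace(-half, half, m)
    X, Y = np.meshgrid(s, s)
    if r <= 0:
        return X, Y
    cx = half - r
    u = np.abs(X) - cx
    v = np.abs(Y) - cx
    corner = (u > 0) & (v > 0)
    uu, vv = u[corner], v[corner]
    rad = np.hypot(uu, vv)
    cheb = np.maximum(uu, vv)
    scale = np.where(rad > 0, cheb / np.maximum(rad, 1e-300), 1.0)
    Xc = X.copy()
    Yc = Y.copy()
    Xc[corner] = np.sign(X[corner]) * (cx + uu * scale)
    Yc[corner] = np.sign(Y[corner]) * (cx + vv * scale)
    return Xc, Yc


@dataclass(frozen=True)
class ImplantModel:
    """Generated implant mesh plus its analytic surface and screw metadata."""

    spec: ImplantSpec
    mesh: TriMesh
    screw_axes: tuple[tuple[np.ndarray, np.ndarray], ...]

    def height_field(self, x, y):
        return self.spec.height_field(x, y)

    @property
    def footprint_outline(self):
        return self.spec.footprint_outline()


def screw_axes_for(spec: ImplantSpec) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    """The two fixation screw axes (origin, unit direction) in implant coords.

    Both screws enter anteriorly through the block centre; the tibial screw
    runs posterior-proximal at ``screw_angle_tibial`` to the horizontal, the
    talar screw posterior-distal at ``screw_angle_talar``.
    """
    centre_height = float(spec.height_field(0.0, 0.0))
    origin = np.array([0.0, 0.0, centre_height / 2.0])
    at = np.deg2rad(spec.screw_angle_tibial)
    aa = np.deg2rad(spec.screw_angle_talar)
    d_tibial = np.array([0.0, -np.cos(at), np.sin(at)])
    d_talar = np.array([0.0, -np.cos(aa), -np.sin(aa)])
    return ((origin, d_tibial), (origin.copy(), d_talar))


def build_implant_mesh(spec: ImplantSpec) -> ImplantModel:
    """Triangulate the implant: flat base at z=0, biquadratic top, filleted walls."""
    if spec.fillet_radius > 0 and spec.mesh_resolution > spec.fillet_radius:
        raise MeshingError(
            "mesh resolution coarser than the fillet radius cannot resolve the corners"
        )
    m = int(round(spec.footprint / spec.mesh_resolution)) + 1
    if m < 3:
        raise MeshingError("mesh resolution too coarse for the footprint")
    X, Y = _rounded_square_grid(spec.half, spec.fillet_radius, m)
    z_top = biquadratic_surface(spec.nodal_heights, X, Y)
    if np.any(z_top <= 0):
        raise MeshingError("height field dips to zero inside the footprint")
    mesh = grid_solid(X, Y, 0.0, z_top, name="fusion-implant")
    return ImplantModel(spec=spec, mesh=mesh, screw_axes=screw_axes_for(spec))
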