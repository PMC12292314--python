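"""Implant-to-bone surface deviation analysis.

The implant's fitting surface is sampled with an even lattice of points
(10,000 by default) across the 24 x 24 mm footprint, and each point's
signed vertical clearance to the tibial and talar articular surfaces is
computed: positive values indicate a gap, negative values overlap.  A fit
passes when every deviation magnitude stays within the surgical tolerance
of 3 mm.

Registration convention: the implant footprint centre and axes are aligned
to the joint frame, and the implant is evaluated in its seated pose -- the
inferior face is assumed prepared to a cylindrical talar-bed template
(sagittal radius ``ImplantSpec.seat_radius``) anchored at the central talar
contact.  The talar-side deviation therefore measures how far the actual
talar surface departs from that bed, and the tibial-side deviation measures
the residual gap between the implant's superior surface and the tibial
plafond.  Deviations are taken along the joint z-axis (the same direction
as the H measurements), not along surface normals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import TriMesh, vertical_intersections_batch
from .implant import ImplantModel, ImplantSpec
from .morphometry import JointFrame

logger = logging.getLogger("talofit")

DEFAULT_N_POINTS = 10_000
DEFAULT_THRESHOLD = 3.0  # mm, acceptable surgical margin
MAX_MISS_FRACTION = 0.01


class CoverageError(RuntimeError):
    """Raised when too many sample lines miss a bone surface."""


@dataclass(frozen=True)
class SurfaceDeviation:
    """Signed deviations (mm) of the fitting surface against one bone."""

    deviations: np.ndarray
    n_misses: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "deviations", np.asarray(self.deviations, dtype=float).reshape(-1)
        )

    @property
    def min(self) -> float:
        return float(self.deviations.min())

    @property
    def max(self) -> float:
        return float(self.deviations.max())

    @property
    def mean(self) -> float:
        return float(self.deviations.mean())

    @property
    def mean_abs(self) -> float:
        return float(np.abs(self.deviations).mean())


@dataclass(frozen=True)
class DeviationReport:
    """Per-point deviations against both bones and the threshold verdict."""

    n_points: int
    tibial: SurfaceDeviation
    talar: SurfaceDeviation
    threshold: float = DEFAULT_THRESHOLD

    @property
    def passed(self) -> bool:
        return bool(
            np.all(np.abs(self.tibial.deviations) <= self.threshold)
            and np.all(np.abs(self.talar.deviations) <= self.threshold)
        )

    @property
    def max_abs_deviation(self) -> float:
        return float(
            max(np.abs(self.tibial.deviations).max(), np.abs(self.talar.deviations).max())
        )

    def summary(self) -> dict:
        d = {"n_points": self.n_points, "threshold_mm": self.threshold, "pass": self.passed}
        for name, s in (("tibial", self.tibial), ("talar", self.talar)):
            d[name] = {
                "min": s.min,
                "max": s.max,
                "mean": s.mean,
                "mean_abs": s.mean_abs,
                "n_misses": s.n_misses,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def sample_fitting_points(spec: ImplantSpec, n: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Evenly distributed sample points on the fitting surface footprint.

    A regular sqrt(n) x sqrt(n) lattice spans the footprint; lattice points
    falling outside the rounded corners are dropped and the lattice is
    densified until at least ``n`` interior points exist, from which ``n``
    are kept by even thinning.  Returns an (n, 2) array of (x, y).
    """
    n = int(n)
    if n < 4:
        raise ValueError("need at least 4 sample points")
    m = int(np.ceil(np.sqrt(n)))
    if m * m != n:
        logger.info("n=%d is not a perfect square; starting from a %dx%d lattice", n, m, m)
    outline = spec.footprint_outline()
    while True:
        s = np.linspace(-spec.half, spec.half, m)
        X, Y = np.meshgrid(s, s)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        inside = shapely.intersects_xy(outline, pts[:, 0], pts[:, 1])
        interior = pts[inside]
        if len(interior) >= n:
            idx = np.round(np.linspace(0, len(interior) - 1, n)).astype(int)
            return interior[idx]
        m += 1


def _surface_heights(
    mesh: TriMesh, xy: np.ndarray, pick: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical-line surface heights; ``pick`` is 'lowest' or 'highest'."""
    hits = vertical_intersections_batch(mesh, xy)
    z = np.full(len(xy), np.nan)
    for i, h in enumerate(hits):
        if len(h):
            z[i] = h[0] if pick == "lowest" else h[-1]
    return z, np.isnan(z)


def compute_deviation(
    implant: ImplantModel,
    tibia: TriMesh,
    talus: TriMesh,
    frame: JointFrame | None = None,
    n: int = DEFAULT_N_POINTS,
    threshold: float = DEFAULT_THRESHOLD,
) -> DeviationReport:
    """Signed vertical deviations of the implant against a tibia/talus pair.

    Per sample point (x, y) in the joint frame:

    * tibial deviation = (tibial articular z) - (implant superior z)
    * talar deviation  = (implant inferior z) - (talar articular z)

    with the implant seated on the talar-bed template anchored at the
    central talar contact.  Lines missing a bone are excluded from the
    summaries; more than ``MAX_MISS_FRACTION`` misses on either bone raises
    :class:`CoverageError`.
    """
    frame = frame or JointFrame.identity()
    spec = implant.spec

    tib_local = TriMesh(frame.to_local(tibia.vertices), tibia.faces, tibia.name)
    tal_local = TriMesh(frame.to_local(talus.vertices), talus.faces, talus.name)

    pts = sample_fitting_points(spec, n)

    # anchor: the talar surface height under the footprint centre
    (centre_hits,) = vertical_intersections_batch(tal_local, [(0.0, 0.0)])
    if len(centre_hits) == 0:
        raise CoverageError("the talus is not under the footprint centre")
    z_anchor = centre_hits[-1]

    z_tib, miss_tib = _surface_heights(tib_local, pts, pick="lowest")
    z_tal, miss_tal = _surface_heights(tal_local, pts, pick="highest")
    for name, miss in (("tibia", miss_tib), ("talus", miss_tal)):
        frac = miss.mean()
        if frac > MAX_MISS_FRACTION:
            raise CoverageError(
                f"{frac:.1%} of sample lines miss the {name} (limit {MAX_MISS_FRACTION:.0%})"
            )

    R = float(spec.seat_radius)
    seat = z_anchor + (np.sqrt(R * R - pts[:, 1] ** 2) - R)
    top = seat + spec.height_field(pts[:, 0], pts[:, 1])

    tibial = SurfaceDeviation(
        deviations=(z_tib - top)[~miss_tib], n_misses=int(miss_tib.sum())
    )
    talar = SurfaceDeviation(
        deviations=(seat - z_tal)[~miss_tal], n_misses=int(miss_tal.sum())
    )
    return DeviationReport(n_points=len(pts), tibial=tibial, talar=talar, threshold=threshold)
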