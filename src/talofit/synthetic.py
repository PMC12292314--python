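"""Synthetic tibiotalar joints with analytically known joint-space fields.

No bone meshes are distributed with the reference cohort, so synthetic
anatomy provides ground truth for every pipeline stage.  A case is built
from nine nodal gap values: the talar dome is a sagittally convex cylinder
(radius 21 mm by default -- the trochlea curves chiefly in dorsiflexion/
plantarflexion; medio-lateral curvature is absorbed into the gap field),
the gap field is the biquadratic interpolant of the nodal gaps, and the
tibial plafond sits at dome + gap.  Both bones are closed solids so generic
mesh predicates (watertightness, even vertical crossings) hold.

Cohorts are drawn with independent per-node normal distributions whose
default means and SDs are those of the packaged reference cohort.  Marginal
statistics only are emulated: real joints have strong inter-node
correlation that the reference table does not report, so synthetic cases
are rougher (more internally discordant) than real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cohort import CohortTable
from .geometry import TriMesh, grid_solid
from .implant import biquadratic_surface
from .morphometry import JointSpaceProfile, default_grid, measure_joint_space

#: Per-node means of the reference cohort (mm), H1..H9.
REFERENCE_NODAL_MEANS = np.array([6.85, 6.41, 5.94, 4.82, 3.72, 3.77, 6.10, 5.62, 5.50])
#: Per-node sample SDs of the reference cohort (mm), H1..H9.
REFERENCE_NODAL_SDS = np.array([2.78, 2.88, 2.16, 2.27, 1.10, 1.71, 2.47, 2.29, 2.39])

DOMAIN_PAD = 4.0  # mm of bone surface beyond the measurement grid
_MIN_GAP = 0.05  # mm floor on the gap field, keeps the shells disjoint
_SLAB = 5.0  # mm of solid bone behind each articular surface


@dataclass(frozen=True)
class SyntheticCaseParams:
    """Ground-truth description of one synthetic joint."""

    nodal_gaps: np.ndarray
    trochlear_radius: float = 21.0
    mesh_resolution: float = 0.5
    rigid_transform: tuple[float, float, float, float, float, float] | None = None
    surface_noise_sd: float = 0.0
    seed: int = 0
    case_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.nodal_gaps, dtype=float).reshape(-1)
        if g.shape != (9,):
            raise ValueError("nine nodal gaps required")
        if np.any(g <= 0):
            raise ValueError("nodal gaps must be positive")
        half_diag = np.hypot(12.0, 12.0)
        if self.trochlear_radius <= half_diag:
            raise ValueError(
                f"trochlear radius must exceed the grid half-diagonal ({half_diag:.2f} mm)"
            )
        if self.surface_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        object.__setattr__(self, "nodal_gaps", g)

    def pose(self) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) of the rigid transform (identity when unset)."""
        if self.rigid_transform is None:
            return np.eye(3), np.zeros(3)
        rx, ry, rz, tx, ty, tz = self.rigid_transform
        R = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        return R, np.array([tx, ty, tz], dtype=float)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Sampling plan for a synthetic cohort of joint-space profiles."""

    n_cases: int = 30
    nodal_means: np.ndarray = field(default_factory=lambda: REFERENCE_NODAL_MEANS.copy())
    nodal_sds: np.ndarray = field(default_factory=lambda: REFERENCE_NODAL_SDS.copy())
    truncation: float = 0.1  # mm lower bound on drawn gaps
    seed: int = 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.nodal_means, dtype=float).reshape(-1)
        sd = np.asarray(self.nodal_sds, dtype=float).reshape(-1)
        if mu.shape != (9,) or sd.shape != (9,):
            raise ValueError("nine nodal means and SDs required")
        if self.n_cases < 2:
            raise ValueError("a cohort needs at least two cases")
        if np.any(sd < 0):
            raise ValueError("nodal SDs must be non-negative")
        object.__setattr__(self, "nodal_means", mu)
        object.__setattr__(self, "nodal_sds", sd)


def talar_dome_height(y, radius: float = 21.0) -> np.ndarray:
    """Height of the cylindrical talar dome: sqrt(R^2 - y^2) - R (apex at y=0)."""
    y = np.asarray(y, dtype=float)
    return np.sqrt(radius * radius - y * y) - radius


def build_case_meshes(
    params: SyntheticCaseParams,
) -> tuple[TriMesh, TriMesh, JointSpaceProfile]:
    """Generate a (tibia, talus, ground-truth profile) triple.

    Deterministic in ``params`` (noise is seeded).  The articular domain
    extends :data:`DOMAIN_PAD` mm beyond the measurement grid; the
    extrapolated gap field is floored at a small positive value so the two
    shells never intersect.
    """
    half = 12.0 + DOMAIN_PAD
    if params.trochlear_radius <= half:
        raise ValueError("trochlear radius too small for the padded domain")
    m = int(round(2 * half / params.mesh_resolution)) + 1
    s = np.linspace(-half, half, m)
    X, Y = np.meshgrid(s, s)

    z_tal = talar_dome_height(Y, params.trochlear_radius)
    gap = np.maximum(biquadratic_surface(params.nodal_gaps, X, Y), _MIN_GAP)
    z_tib = z_tal + gap

    talus = grid_solid(X, Y, z_tal.min() - _SLAB, z_tal, name="synthetic-talus")
    tibia_bottom_first = grid_solid(X, Y, z_tib, z_tib.max() + _SLAB, name="synthetic-tibia")
    tibia = tibia_bottom_first

    if params.surface_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        tibia = TriMesh(
            tibia.vertices + np.column_stack(
                [np.zeros((tibia.n_vertices, 2)),
                 rng.normal(0.0, params.surface_noise_sd, tibia.n_vertices)]
            ),
            tibia.faces,
            tibia.name,
        )
        talus = TriMesh(
            talus.vertices + np.column_stack(
                [np.zeros((talus.n_vertices, 2)),
                 rng.normal(0.0, params.surface_noise_sd, talus.n_vertices)]
            ),
            talus.faces,
            talus.name,
        )

    R, t = params.pose()
    if params.rigid_transform is not None:
        tibia = tibia.transformed(R, t)
        talus = talus.transformed(R, t)

    truth = JointSpaceProfile(
        case_id=params.case_id or f"synthetic-{params.seed}", H=params.nodal_gaps
    )
    return tibia, talus, truth


def generate_cohort(
    spec: SyntheticCohortSpec, full_path: bool = False
) -> tuple[CohortTable, list[SyntheticCaseParams]]:
    """Draw a synthetic cohort of joint-space profiles.

    Each case's nine gaps are drawn independently from
    Normal(nodal_means[j], nodal_sds[j]) and clipped below at
    ``spec.truncation``.  With ``full_path=True`` every case's meshes are
    built and measured through the morphometry pipeline; the default fast
    path records the drawn ground-truth values directly.
    """
    rng = np.random.default_rng(spec.seed)
    draws = rng.normal(spec.nodal_means, spec.nodal_sds, size=(spec.n_cases, 9))
    draws = np.maximum(draws, spec.truncation)

    params_list = [
        SyntheticCaseParams(
            nodal_gaps=draws[i],
            seed=int(rng.integers(0, 2**31 - 1)),
            case_id=f"S{i + 1:02d}",
        )
        for i in range(spec.n_cases)
    ]
    if full_path:
        profiles = []
        grid = default_grid()
        for p in params_list:
            tibia, talus, _ = build_case_meshes(p)
            profiles.append(
                measure_joint_space(tibia, talus, grid=grid, case_id=p.case_id)
            )
    else:
        profiles = [
            JointSpaceProfile(case_id=p.case_id, H=p.nodal_gaps) for p in params_list
        ]
    table = CohortTable(tuple(profiles), provenance=f"synthetic cohort seed={spec.seed}")
    return table, params_list
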