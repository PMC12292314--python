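# Methods

## Coordinate frame and measurement model

All geometry is in millimetres in a right-handed frame with +z proximal
along the tibial shaft, +y anterior and +x lateral; the origin sits at the
centroid of the distal tibial articular surface.  This emulates a standing
posture: the tibia is vertical, at 90° to the plantar line from the head of
the fifth metatarsal to the medial calcaneal tuberosity.  When those
landmarks are supplied, `build_joint_frame` orthonormalises shaft and
plantar directions into the frame; otherwise meshes are assumed
pre-aligned and the identity frame is used.  The articular centroid is
estimated as the area-weighted centroid of downward-facing tibial
triangles, falling back to the lowest 10% vertex band for open sheets.

Joint-space heights are vertical clearances: at each node of the 3×3 grid
(pitch 12 mm), H = (lowest tibial crossing) − (highest talar crossing) of
the vertical line through the node.  Vertical-line/mesh intersection is an
exact 2-D barycentric point-in-triangle test per triangle, vectorised over
query points; crossings closer than 1e-9 mm merge (a hit on an edge shared
by two conforming triangles counts once), zero-area triangles are skipped
with a warning, and triangles parallel to the line cannot produce a
transversal crossing and are ignored.  Left-sided joints are mirrored about
the sagittal plane before measurement so lateral/medial columns pool
consistently across sides.

Node labels: H1–H3 anterior row, H4–H6 middle, H7–H9 posterior; H1/H4/H7
lateral column (x = −12), H3/H6/H9 medial (x = +12), H5 central.

## Cohort statistics and representativeness

Per node, the cohort mean and *sample* SD (denominator n − 1) are computed
over all cases; n ≥ 2 is required.  The representativeness score is
V_sum = Σⱼ |H̄ⱼ − Hⱼ| with the per-column means (not a grand mean) and with
the candidate case *included* in the means — this convention reproduces the
packaged reference cohort's printed V_sum values to within the 0.01 mm
rounding of its cells.  Ties at the minimum are broken by table order.  A
zero height (present in the reference table) is retained as a legitimate
datum with a logged warning; negative heights (interpenetrating
segmentations) likewise warn but are kept.

## Normality verification

Each node's 30 heights are tested against a normal law with parameters
estimated from the same sample (mean, n−1 SD).  The statistic is the
two-sided ECDF supremum D = maxᵢ max(|i/n − F(x₍ᵢ₎)|, |(i−1)/n − F(x₍ᵢ₎)|),
which equals the true sup over all x.  The p-value uses the asymptotic
Kolmogorov distribution Q(λ) = 2Σ_{k≥1}(−1)^{k−1}e^{−2k²λ²} at
λ = (√n + 0.12 + 0.11/√n)·D.  Plugging estimated parameters into the plain
K-S formula makes the test conservative (its null rejection rate at the
0.05 level is far below 5%; the suite asserts ≤ 7% over 1,000 simulated
n=30 samples).  The statistically corrected Lilliefors variant is available
via `lilliefors=True` (delegated to statsmodels) for users who want a
calibrated test rather than fidelity to the plain formula.

Q-Q data standardise the sample by (x − mean)/SD and pair the sorted values
with normal quantiles at plotting positions (i − 0.5)/n — symmetric and
well-defined at small n.  The 3σ report standardises every value per node
and flags containment iff max |z| ≤ 3.  On the packaged reference cohort
this check *fails by a hair*: one H5 value (7.08 mm, case 5) lies 3.05 SDs
above its node mean, so `within_3sigma` is honestly `False` there; every
other of the 270 values is within 3σ.

## Implant surface model

The implant is a 24 × 24 mm block: flat inferior face at z = 0, superior
face equal to the gap height field.  The height field is the biquadratic
tensor-product Lagrange polynomial through the 3×3 nodal grid — the unique
minimal-degree surface interpolating nine nodes, hence reproducible without
further knobs.  The four vertical edges are rounded by a 5 mm fillet,
implemented as 2-D corner rounding of the footprint (closed-form area
576 − (4 − π)·25 ≈ 554.54 mm²); top/bottom edge fillets are omitted so the
printed 24 × 24 footprint semantics are preserved.  Meshing maps a regular
grid onto the rounded square with the radial Chebyshev corner map and
extrudes between the flat base and the height field, producing a
combinatorially watertight solid at any resolution (default 0.5 mm; a
resolution coarser than the fillet radius is rejected).  Screw channels are
metadata, not boolean cuts: two axes through the block centre, entering
anteriorly, at 35° (tibial, directed proximally) and 30° (talar, distally)
to the horizontal plane; the diameter is configurable (default 4 mm)
because it is a manufacturing, not a morphometric, parameter.

Whether the inferior face should be flat or talar-conforming is left
configurable in spirit: the block geometry keeps the flat face, while fit
evaluation (below) assumes a talar-bed template.

## Deviation analysis and registration convention

The fitting surface is sampled with a regular √n × √n lattice over the
footprint (default n = 10,000, pitch ≈ 0.24 mm); lattice points outside the
rounded corners are dropped and the lattice densified until n interior
points exist, then thinned evenly to exactly n.  Deviations are measured
along the joint z-axis — the same direction as H — rather than along
surface normals; this makes self-consistency exact and the sign convention
unambiguous (positive = gap, negative = overlap).  Normal-projection, as
commercial inspection software may use, would differ by a cosine factor on
steep regions.

Registration: the implant's footprint centre and axes align with the joint
frame, and the implant is evaluated *seated*: its inferior face is assumed
prepared to a cylindrical talar-bed template (sagittal radius
`seat_radius`, default 21 mm) anchored at the talar surface under the
footprint centre.  Then, per sample point,

* tibial deviation = tibial articular z − (seat + height field), and
* talar deviation = seat − talar articular z.

A rigid flat-bottomed block cannot sit flush on a convex dome (the dome
falls ≈ 3.8 mm across the footprint at radius 21 mm), so a seated-pose
evaluation is the only convention under which an implant built from a
case's own profile shows near-zero deviation on *both* surfaces — the
self-consistency property the test suite enforces (< 0.05 mm mean absolute
deviation at default resolutions).  Sample lines that miss a bone are
excluded and counted; more than 1% misses on either bone is a coverage
error.  The pass verdict requires every |deviation| ≤ 3 mm, the accepted
surgical margin.

## Synthetic anatomy

A synthetic case is defined by its nine nodal gaps: the talar dome is a
sagittally convex cylinder (default radius 21 mm — the trochlea curves
chiefly in the flexion plane; medio-lateral curvature is absorbed into the
gap field), the gap field is the biquadratic interpolant of the nodal gaps
(floored at 0.05 mm where extrapolation beyond the grid could dip), and the
tibial plafond is dome + gap.  Both bones are closed solids over a domain
padded 4 mm beyond the grid, so watertightness and even-crossing invariants
hold.  Optional vertex noise (z-direction, seeded) and a 6-dof rigid pose
exercise robustness and invariance.  Generation is deterministic in the
parameters.

Cohorts draw each node independently from Normal(mean, SD) with the
packaged reference cohort's per-node statistics as defaults, clipped below
at 0.1 mm (the clip probability is ≤ 5·10⁻⁴ per node at those parameters).
Only *marginal* statistics are emulated: real joints have strong inter-node
correlation (a uniformly wide or narrow joint) that a marginal table cannot
supply.  Consequently synthetic cases are internally rougher than real
ones, and the rate at which a cohort-mean implant fits a random synthetic
case within 3 mm everywhere (≈ 10–15%) understates the fit rate to be
expected on real anatomy, where the three published test cases all passed.
Passing tests therefore demonstrate correctness of the measurement, the
statistics and the geometry — not a clinical fit rate.

## Numerical choices and problem sizes

* Mesh resolutions: 0.5 mm default for bones and implant; measurement error
  against analytic ground truth is < 0.05 mm there and shrinks
  quadratically with resolution (chordal error of the curved surfaces).
  The test suite uses 0.45–1.7 mm and lattices of 400–2,500 points where a
  full 10,000-point run adds nothing to the property under test.
* Vertical-hit merging tolerance 1e-9 mm; barycentric inclusion tolerance
  1e-10 (boundary hits count as inside for both adjacent triangles, then
  merge).
* Frame orthonormality enforced to 1e-9; degenerate landmark
  configurations (collinear, coincident) raise alignment errors rather
  than silently producing a skewed frame.
* K-S p-values are clamped to [0, 1]; constant samples raise a
  degenerate-sample error rather than returning D = NaN.

## Known limitations

* No CT segmentation: input is surface meshes; no mesh repair beyond
  skipping degenerate faces.
* The central grid planes are placed at the distal articular centroid; the
  anatomical definition of "central" is otherwise under-determined.
* Deviations use z-projection, not closest-point distance.
* No inter-node correlation model in the cohort generator (see above).
* Screw hardware, threads, plates and any finite-element or load analysis
  are out of scope; screw axes are design metadata only.
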