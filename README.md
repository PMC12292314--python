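# talofit

Tibiotalar joint-space morphometry and anatomically conforming
fusion-implant design.

Ankle arthrodesis fuses the tibiotalar joint after cartilage debridement.
Fusion succeeds when the fixation preserves a large, compressed bone-to-bone
contact area, which is why a spacer implant that matches the joint's natural
curvature is attractive.  `talofit` implements the measurement and design
pipeline behind such an implant, for biomechanics researchers and implant
engineers working from CT-derived bone surface meshes:

1. **Morphometry** — nine joint-space heights H1–H9 are measured on a 3×3
   grid over the joint (grid pitch 12 mm: a central point plus ±12 mm
   offsets antero-posteriorly and medio-laterally), as the vertical
   clearance between the tibial plafond and the talar dome in a standing
   joint frame.  H1/H2/H3 form the anterior row, H1/H4/H7 the lateral
   column, H5 the centre.
2. **Cohort database** — cases are pooled; per node *j* the cohort mean
   H̄ⱼ and sample SD are computed, and each case is scored by

   V<sub>sum</sub> = Σⱼ |H̄ⱼ − Hⱼ|,  j = 1…9 (mm).

   The case with minimal V<sub>sum</sub> is the cohort's representative
   morphology.  A packaged 30-case reference cohort ships with the library.
3. **Normality verification** — per-node one-sample Kolmogorov–Smirnov
   tests (D = sup |Fₙ(x) − F(x)| against a normal with sample-estimated
   parameters; asymptotic p-value with the small-sample correction
   λ = (√n + 0.12 + 0.11/√n)·D), Q-Q data at plotting positions
   (i − 0.5)/n, and a 3σ containment report.
4. **Implant design** — a 24 × 24 mm block whose superior surface is the
   unique biquadratic (tensor-product Lagrange) surface through the nine
   cohort-mean heights, with a 5 mm corner fillet and two fixation screw
   axes (35° tibial, 30° talar to the horizontal) stored as metadata.
   Export as watertight STL.
5. **Deviation analysis** — 10,000 evenly distributed points across the
   fitting surface; signed vertical deviations to the tibial and talar
   surfaces (positive = gap, negative = overlap) against a 3 mm surgical
   tolerance.
6. **Synthetic anatomy** — parametric tibia/talus mesh pairs with an
   analytically known gap field (cylindrical talar dome + biquadratic gap)
   provide ground truth for every stage, including whole cohorts drawn from
   the reference per-node distributions.

## Worked example

```python
import numpy as np
import talofit as tf

cohort = tf.load_reference_cohort()
summary = tf.summarize_cohort(cohort)
print("per-node means (mm):", np.round(summary.H_ave, 2))
print("per-node SDs  (mm):", np.round(summary.H_sd, 2))

rep = tf.select_representative(cohort)
print(f"representative case: {rep.representative_case} "
      f"(V_sum = {rep.v_min:.2f} mm; worst case scores {rep.v_max:.2f} mm)")

for res in tf.cohort_normality(cohort)[:3]:
    print(f"H{res.node}: K-S D = {res.D:.3f}, p = {res.p_value:.3f}")

implant = tf.build_implant_mesh(tf.ImplantSpec.from_summary(summary))
print(f"implant: watertight={implant.mesh.is_watertight()}, "
      f"volume={implant.mesh.volume():.1f} mm^3")

tibia, talus, _ = tf.build_case_meshes(
    tf.SyntheticCaseParams(nodal_gaps=summary.H_ave, seed=1)
)
report = tf.compute_deviation(implant, tibia, talus, n=10_000)
print(f"fit vs mean-shaped joint: max |deviation| = "
      f"{report.max_abs_deviation:.3f} mm, pass(<=3 mm) = {report.passed}")
```

prints

```
per-node means (mm): [6.85 6.41 5.94 4.82 3.72 3.77 6.1  5.62 5.5 ]
per-node SDs  (mm): [2.78 2.88 2.16 2.27 1.1  1.71 2.47 2.29 2.39]
representative case: 30 (V_sum = 7.90 mm; worst case scores 27.70 mm)
H1: K-S D = 0.078, p = 0.990
H2: K-S D = 0.102, p = 0.895
H3: K-S D = 0.102, p = 0.897
implant: watertight=True, volume=2539.0 mm^3
fit vs mean-shaped joint: max |deviation| = 0.003 mm, pass(<=3 mm) = True
```

The first two lines are the cohort's nodal statistics: the joint space is
deepest anteriorly and laterally (H1 ≈ 6.9 mm) and shallowest centrally
(H5 ≈ 3.7 mm) — a concave-lens shape.  Case 30 deviates least from those
means (7.90 mm summed over nine nodes), so it is the representative joint.
All nodes are compatible with per-node normality (p > 0.05).  The implant
built from the means fits a mean-shaped joint to within measurement noise,
far inside the 3 mm surgical tolerance.

The same pipeline is scriptable from the shell:

```bash
talofit simulate --n 30 --seed 42 --out-dir cohort/
talofit summarize --cohort cohort/cohort.csv --out summary.json
talofit representative --cohort cohort/cohort.csv --out rep.json
talofit normality --cohort cohort/cohort.csv --out normality.json
talofit design --summary summary.json --resolution 0.5 --out implant.stl
talofit deviate --summary summary.json --tibia t.stl --talus a.stl --out report.json
talofit measure --tibia t.stl --talus a.stl --out profile.csv
```

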