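# Methods

## The measurement model

The object under test is a full-arch surface scan of a maxillary model
carrying a metal reference bar between the second molars.  The bar's
length between its two outer (vestibular) end faces is certified by
tactile CMM metrology; the default, 55.066 mm, is a configuration value
(`reference_length_mm`).  Only the outer portion (≤ 20 mm) of each bar end
appears in a scan: the featureless middle of the bar defeats optical
frame-stitching, so capturing it would itself distort the scan.  The
evaluation therefore never sees the bar as one object — it measures the
*relative pose* of the two captured ends and compares it with the
certified length.

All geometry is computed in millimetres in a right-handed model frame:
X transversal (along the bar, positive toward quadrant 1), Y
anterior-posterior, Z vertical.  The frame is part of the scan
configuration (origin plus axis rows); scans are expressed in it before
any region is selected.  Deviations are converted to µm only at reporting.

Per end q ∈ {1, 2} three planes are fitted to configured mesh regions:

* APq, PPq — the anterior and posterior faces adjacent to the bar's upper
  edge (they must not be parallel; their intersection *is* the edge);
* VPq — the outer end face.

The construction chain is: Vq = APq ∩ PPq (edge line), Pq = Vq ∩ VPq
(edge point), VP2′ = VP2 shifted by the reference length toward quadrant 1
along ±X, P2′ = V2 ∩ VP2′.  The measurands are

* V_E = P1 − P2′ per axis (µm) and its Euclidean norm ("VE"),
* ΔL = ‖P2 − P1‖ − L (µm),
* α_overall = arccos(V̂1·V̂2)·180/π, plus α_coronal and α_axial: the same
  arccos applied to the (X, Y) and (X, Z) components respectively.

For a perfect scan P2′ coincides with P1 and every measurand is zero.  If
end 2 is rigidly translated by t, P2′ inherits the translation exactly, so
V_E = −t; a torsion of end 2 about Z by θ appears as
α_overall ≈ α_coronal ≈ θ with α_axial ≈ 0.  These closed-form
propagations are the package's recovery oracles.

Naming note: the anatomical mapping calls XZ the coronal plane, yet the
conventional "coronal" angle uses the (X, Y) components and the "axial"
angle the (X, Z) components.  The package implements the formulas exactly
as printed in the field's usage and keeps the names without resolving the
inconsistency.

## Conventions and numerical choices

* **Plane fitting** is orthogonal least squares: the normal is the
  smallest-singular-vector of the centred point cloud (total least
  squares), the plane passes through the centroid.  This is the scripted
  analogue of an interactive "contact feature" plane in mesh-inspection
  software, whose exact algorithm and tolerances are not published.
* **Sign conventions.**  arccos-based angles would report ~180° for a
  flipped direction, so every plane normal is oriented by a caller hint
  (outward of the bar surface) and every line direction is canonicalised
  to a positive X component (falling back to Y, then Z below 1e-9).  The
  VP2 shift direction is ±X with the sign of (P1 − P2)·X̂ ("toward
  quadrant 1").  Signed V_E components are only comparable between runs
  using the same frame configuration.
* **ΔL** is defined as ‖P2 − P1‖ − L.  The length measure is consistent
  with ΔL tracking the X component of V_E when the bar is X-aligned.
* **"VE"** (the scalar) is the Euclidean norm of V_E — the only
  nonnegative scalar consistent with VE ≥ max |component|.
* **Tolerances:** parallelism cutoffs at 1e-6 on normalised cross/dot
  products; geometric identities asserted at 1e-9 mm; arccos arguments
  clamped to [−1, 1].  Degenerate inputs (collinear fits, parallel
  AP/PP, line parallel to plane, zero projections) raise typed errors
  annotated with the quadrant and scan id.

## The synthetic scan generator

The generator replaces the physical model and scanner.  It emulates what
the measurand can see of a full-arch scan:

* **Geometry.**  Two bar-end prisms whose outer faces are exactly
  `bar_length_mm` apart, plus a coarse arch ribbon (swept rectangular
  section) placed below the bar.  The bar cross-section is a square
  standing on its corner, so the two upper 45° faces play the roles of the
  anterior/posterior faces and intersect in the upper bar edge; an
  axis-aligned square would make AP ∥ PP and the construction undefined.
  Tooth anatomy is irrelevant to the measurand and omitted.  Each
  component is watertight; generation is deterministic.
* **Distortion model.**  A rigid transform of the end-2 vertex set
  (rotation about its centroid in degrees about X, Y, Z, then translation
  in µm) plus isotropic Gaussian noise (µm) on every vertex.  Rationale:
  stitching error accumulated along the arch is visible to the bar
  metrology only as the relative rigid pose of end 2 versus end 1, so a
  rigid per-end error reproduces every measurand the pipeline reports.
  Smooth intermediate warps of the arch, scanner-specific artefacts and
  the optical acquisition itself are deliberately not modelled — passing
  recovery tests shows the *pipeline* is correct, not that any real
  scanner behaves like the simulator.
* **Strategy profiles.**  Nine profiles (segmentation F/H/S × movement
  L/Z/C) draw per-scan distortions from Gaussians.  The defaults use a
  common systematic offset (bar reading short along X, sagging in Z) with
  dispersion scale factors F 1.0 / H 1.2 / S 1.5 and L 1.0 / Z 2.5 /
  C 1.3 on baseline translation scales (60, 60, 75) µm and rotation scales
  (0.06, 0.12, 0.15)°, vertex noise σ = 5 µm.  The magnitudes are of the
  order reported for full-arch IOS scans (tens to hundreds of µm,
  fractions of a degree) and encode the qualitative finding that linear
  full-jaw scanning is most precise and zig-zag least; they are simulator
  configuration, not measured claims.
* **Mesh density.**  Target edge length 0.5 mm.  Real IOS meshes are
  denser still (sub-0.2 mm); at 0.5 mm each fitted region holds several
  hundred vertices, which keeps plane-fit noise (and its 55 mm lever-arm
  amplification into P2′) well below the injected distortions while the
  model stays at ~3k vertices.
* **Guard band.**  The side faces carry no vertex rows within 2 mm of the
  outer end faces.  Region selectors are fixed boxes in the model frame;
  the guard band lets the end-face boxes be ~0.9 mm thick, so they
  tolerate end displacements up to that order without ever catching
  side-face vertices.  This is the generator's answer to the ragged,
  partially captured region borders of real scans; with real data the box
  extents are the user's responsibility.
* **Fast path.**  `simulate_strategy_study(fast=True)` propagates each
  drawn distortion through the exact analytic face planes instead of
  meshing — identical geometry, no fitting, ~1000× faster.  Vertex noise
  is omitted there: its effect on a fitted plane scales with σ/√n and is
  sub-µm at the defaults.  The fast path powers the statistics-layer
  simulations (e.g. 1000 null studies for type-I calibration); the mesh
  path is used wherever fitting itself is under test.

## Statistics

Trueness comparisons operate on the signed per-scan deviations, precision
on their dispersion, parameter by parameter (ΔL, VE, VE_x, VE_y, VE_z in
µm; α_overall, α_coronal, α_axial in degrees).

* Descriptives per group: mean, sample SD (n−1), median, min/max, and a
  t-based 95% CI of the mean, M ± t(0.975, n−1)·SD/√n.  The t convention
  reproduces published per-strategy CI bounds from their printed M and SD
  at n = 25 to the printed precision, which is how it was selected.
* Normality: Shapiro-Wilk (decision criterion at α = 0.05) plus the
  Kolmogorov-Smirnov check, reported both as the Lilliefors variant
  (estimated parameters — the usual software default) and as the plain
  one-sample KS, since reports rarely say which was run.
* Omnibus: Kruskal-Wallis with tie correction, χ² p with k−1 df.  An
  all-identical input is vacuous by convention (H = 0, p = 1).
* Pairwise trueness: two-sided Mann-Whitney U — exact when
  min(n₁, n₂) ≤ 8 with no ties, otherwise the normal approximation with
  tie and continuity corrections — at the Bonferroni threshold
  family_α/m rounded to 3 decimals (0.05/3 → 0.017).
* Pairwise precision: Brown-Forsythe (Levene on absolute deviations from
  group medians) at the same threshold.  A median-centred dispersion test
  is robust to the non-normality these deviations typically show; the
  point estimate of precision is the SD itself (ISO 5725-1).
* Comparison families: for the full 3×3 strategy grid, the six
  factor-level triples (movements within a segmentation, segmentations
  within a movement), m = 3 pairs each.  Pairs spanning families (e.g.
  FL vs HZ) are never tested and are treated as non-significant in the
  letter display; consequently a group can only ever "separate" from the
  groups it was actually compared with.  Any other strategy set falls
  back to a single all-pairs family.
* Letters: insert-and-absorb compact letter display; sharing a letter is
  equivalent to non-significance for every tested pair, and the report
  builder verifies that equivalence on every report it assembles.

## Problem sizes

The simulated study is 9 × 25 = 225 scans, matching the reference design.
Recovery checks average 25 noisy mesh replicates (σ = 5 µm).  Type-I
calibration runs 1000 fast-path null studies.  Oracle cross-checks use
≤ 200-point clouds for plane fitting and total n ≤ 10 for the exhaustive
rank-test enumerations.

## Known limitations

* The rigid per-end distortion model cannot represent within-end bending
  or scale errors; region-level plane fits would average such effects.
* Fixed box selectors assume the scan is roughly in the configured frame;
  grossly misplaced scans need a coarse pre-alignment step that is out of
  scope here (no ICP/best-fit is provided, by design).
* The letter display is family-limited (see above): it encodes only the
  comparisons the design actually ran.
* Signed deviations are frame-dependent; only magnitudes and dispersions
  are comparable across differently configured sessions.
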