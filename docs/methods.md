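# Methods

## Measurement model

A scapula arrives as a labeled triangle surface (mm) — the product of a CT
segmentation — plus landmark picks.  Three constructions produce the
inclination:

**Scapular frontal plane.**  Total-least-squares plane (orthogonal-distance
regression via the eigen-structure of the centered vertex cloud) over every
vertex labeled `body`, `spine` or `fossa` — i.e. the whole scapula except
the glenoid, acromion and coracoid, whose bulky processes would bias the
plane.  The normal is oriented anteriorly using region centroids: lateral ≈
body→glenoid centroid, superior ≈ body→spine/fossa centroid, anterior
completing the triad with a handedness set by laterality.

**Transverse axis.**  `y_axis`: the spine/body boundary is the set of
vertices sharing a mesh edge with a vertex of the other label (labels are
the declared input; no geometric ridge detection), fit with a TLS line and
re-anchored at the glenoid center.  `gt_line`: glenoid center → trigonum.
`bflf`: TLS line through the five supraspinatus-fossa picks.  All
transverse axes are oriented to point laterally.

**Glenoid mediolateral axis.**  The glenoid-labeled vertices are fit with a
sphere (algebraic linear seed, then geometric least squares on
`Σ(‖p−c‖−r)²`); the axis runs from the glenoid center (midpoint of the
picked upper/lower apexes) toward the sphere center, i.e. medially.

**Angle and sign.**  Both axes are projected onto the frontal plane; the
glenoid axis is reversed so both representatives point laterally; the
inclination is the signed angle between them.  The sign convention — never
formalised in the planning literature, which just reports superior tilt as
positive — is made explicit by a measurement frame: the superior reference
is the projection of (glenoid center − inferior angle), orthogonalized
against the lateral direction, and the angle is positive when the glenoid's
lateral direction tilts toward superior.  The construction is invariant
under rigid motions, uniform scaling, and left/right side (verified by
tests; left scapulae are handled by the frame's handedness, never by
mirroring data).

In the full study pipeline the frontal plane, Y-axis and glenoid
mediolateral axis are *software-side*: computed once per case from the mesh
and the exact glenoid center.  A rater's picks enter only the manual
transverse axes (GT-line through the rater's apex-midpoint and trigonum;
BFLF through the rater's fossa picks).  When measuring a single case from
one landmark file (`glenax measure`), that file's apex midpoint is the one
shared glenoid center for everything.

## Synthetic scapulae

The generator emulates the statistical structure of a measurement study,
not scapular anatomy.  The blade (body + spine band + fossa band) is a
*flat* plate so the frontal plane is exact and all truths are closed-form;
the spine root line is straight; the glenoid is a spherical cap cut from a
known sphere whose axis makes exactly the requested angle with the root
line.  Consequences:

* every method's ground truth is analytic: `y_axis` reads the true
  inclination a; `gt_line` reads `a + atan(trigonum_offset_si / blade_length)`;
  `bflf` reads `a − fossa_tilt_deg`;
* zero-noise recovery to 1e−3° is a meaningful end-to-end check of the
  whole pipeline;
* what passing tests do **not** show: robustness to blade curvature,
  segmentation error, osteophytes, eroded (arthritic) glenoids, or
  ambiguous spine/body label boundaries on real meshes.  Real-cohort
  magnitudes (means, biases, pairwise rates) are cohort-specific and are
  not claimed.

Geometry defaults (adult scapula scale): blade length 105 mm (trigonum to
glenoid center), blade height 140 mm (70% body below the root line, 20%
fossa above the 12 mm spine band), glenoid sphere radius 30 mm with a 70°
cap aperture (≈35 mm superoinferior glenoid extent), mesh resolution 4 mm,
fossa picks at 25–85% of the blade length.  Small off-plane acromion and
coracoid patches exist so their exclusion from the frontal plane is
exercised.

## Noise and cohort model

Per-rater landmark noise (Gaussian, mm): trigonum 5.0 superoinferior /
2.0 orthogonal — the trigonum is the landmark whose picks disperse mostly
along the superoinferior axis, and 5 mm matches the positioning-error scale
used in the power analysis; fossa picks 2.0 isotropic; apexes 1.0 isotropic
(the glenoid center is known to be the more stable pick).  Four raters by
default.

Per-case morphology: trigonum superoinferior offset from a mixture — 90%
N(0, 2 mm) and 10% "worst-case" N(0, 10 mm), modeling the minority of
scapulae whose medial-border anatomy makes the trigonum genuinely
ambiguous; fossa-line tilt N(0, 2.5°), modeling per-case fossa morphology
(anchored to the observed dispersion between fossa-based and automatic
measurements; without it a fossa-based method could never be the discordant
one, which real cohorts show it can).  True inclinations are uniform on
[−15°, 21°], the span observed for automatic measurements in normal and
arthritic shoulders; test grids extend to [−20°, 28°] to cover the manual
methods' wider range.  All of these are config-overridable
(`StudyConfig` / YAML); the defaults are the package's stated study
conditions, not fitted quantities.

## Statistics

* **ICC(2,1)**: two-way random effects, absolute agreement, single rater —
  chosen because the question is interchangeability of raters' absolute
  angles, and because an automatic method with identical rater columns must
  report exactly 1.00.  Mean squares are computed from residuals
  `x_ij − rowmean_i − colmean_j + grand`, which yields an exact 1.0 (not
  1 − ε) for identical columns.  95% CI by the McGraw–Wong F-distribution
  method.  Zero between-case variance raises an error (the coefficient is
  undefined, not zero).
* **Bland–Altman**: bias ± 1.96·SD of differences (sample SD, n−1).  The
  "95% CI at 5°" decision threshold is read as the half-width of the
  limits of agreement.
* **Lin's CCC**: population (1/n) moments, per Lin's original estimator;
  `C_b` is computed directly from moments and `ccc := r·C_b`, so the
  LoP + LoA = 100% identity holds to floating-point rounding.  The split
  `1−ccc = (1−r) + r(1−C_b)` attributes `(1−r)` to precision and
  `r(1−C_b)` to accuracy; the percentage split is not uniquely determined
  by the verbal definition of LoP/LoA and this factorisation is the
  package's documented choice.
* **Staged workflow**: Pearson gate `r > 0.7`; then Bland–Altman against
  |bias| ≤ 3° and half-width ≤ 5° (concordant ⇒ Lin deliberately not
  computed); otherwise the Lin decomposition labels the discordance
  precision- or accuracy-dominant at the 50% split.
* **Power analysis**: two-sample normal approximation (the one-sample
  variant would give 32 rather than 63 for the reference parameters).
* **Study pipeline**: ICC uses the per-rater (pre-averaging) values;
  between-method comparisons and outlier counts use rater-averaged values.
  Per-case measurement failures are caught, counted and excluded rather
  than aborting a batch.

## Numerical choices

* Plane/line fits: SVD of the centered cloud; degenerate inputs (collinear
  for planes, coincident for lines, coplanar for spheres) are detected via
  singular-value ratios and rejected with descriptive errors.
* Sphere fit: Levenberg–Marquardt refinement with tolerances at machine
  precision (1e−15), far below the 1e−10 mm convergence contract; the
  algebraic-only fit is biased on shallow caps, hence the refinement.
* Direction signs: fits canonicalize (first nonzero component positive);
  anatomical orientation (lateral, superior, anterior) is applied by the
  measurement layer so the geometric kernels stay anatomy-agnostic.
* Angles are computed in radians internally and reported in degrees;
  human-readable reports round to 0.1° (angles), 0.01 (coefficients),
  integer percent; CSV/JSON outputs keep full precision.
* Projection of a direction onto a plane fails when the direction is
  within 1e−6 rad of the normal; `signed_angle` requires its inputs in the
  reference plane to 1e−6 and returns values in (−180°, 180°].
* All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; cohorts and studies are bit-reproducible.

## Problem sizes

The default study (82 cases × 4 raters × 3 methods at 4 mm mesh
resolution, ≈1,200 vertices/case) runs in well under a second; the
replicate-based stability checks use 50 such studies.  The Monte-Carlo
check of the rater-noise model uses 10,000 simulated picks.

## Known limitations

* The flat-blade generator cannot probe curvature-induced frontal-plane
  bias, and its label boundary is perfectly clean — both idealisations.
* The lone-outlier counts under the default mixture are small (≈2–4 per
  82-case study), so count-based orderings between methods fluctuate
  across replicates; rate-based quantities are more stable.
* The ICC confidence interval assumes the two-way ANOVA model; it is not a
  bootstrap and inherits that model's normality assumptions.
* PLY stores coordinates as 32-bit floats; round-trips are exact only for
  float32-representable coordinates (documented in `write_mesh`).
* Laterality is not representable in PLY/STL/OBJ and must accompany the
  mesh (function argument / file naming).
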