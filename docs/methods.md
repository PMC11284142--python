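# Methods

`tibtorsion` measures pediatric tibial torsion from labeled 2D landmarks
traced on two axial CT sections per tibia, and provides the simulation and
statistical machinery needed to validate such a measurement protocol when
no raw landmark data are available.

## Angle measures

All geometry lives in image coordinates: x to image-right, y anterior,
millimetres. Every measured object is an *undirected axis*, so angles are
defined modulo 180° and folded into (−90°, 90°]. Four angles to the image
horizontal are computed per tibia:

* **PTTA** — proximal transtibial angle: a circle is fitted to each of the
  medial and lateral tibial-plateau arcs; the axis joins the two centers.
* **PMTPA** — posterior margin tibial plateau angle: total-least-squares
  line through the posterior-margin points.
* **IMA** — intermalleolar angle: axis through the centroids of the
  medial and lateral malleolar point clouds. Centroids (rather than
  fitted circle centers) are used because malleolar arcs are short and a
  circle fit on them is unstable.
* **TA** — talar angle: total-least-squares tangents to the medial and
  lateral talar facets, their bisector, and the perpendicular to that
  bisector (the talar axis, approximating the tibiotalar joint's
  geometric axis).

Torsion is distal minus proximal, external torsion positive:
`TTA1 = IMA − PMTPA`, `TTA2 = TA − PMTPA`. This composition is the only
one that reproduces the published mean torsion values from the published
per-method means (e.g. 23.0 − (−7.6) = 30.6° ≈ the reported 30.5°).
PTTA is retained as a measure even though the torsion compositions use
PMTPA, so the proximal-method comparison itself is reproducible.

### Numerical choices

* **Circle fit.** Algebraic (Kåsa) least squares provides a closed-form
  start; deterministic Gauss–Newton iterations on the true radial
  residuals then remove the algebraic partial-arc bias, which reaches
  tenths of a millimetre on ~120° arcs with realistic placement noise —
  the same order as the landmark noise itself, hence not negligible. The
  fit is exact (zero residual, no iteration) on points from one circle.
* **Line fit.** Orthogonal (total) least squares via SVD, because facet
  and margin tracings can be near-vertical where ordinary regression is
  biased. Equivalent to the principal eigenvector of the 2×2 scatter
  matrix.
* **Bisector branch.** Two bisectors of a pair of axes exist, 90° apart.
  We take the bisector of the *acute* angle between the facet tangents:
  for near-parallel, near-sagittal talar facets this is the
  anteroposterior talar midline, and — unlike a "closer to vertical"
  heuristic — the choice commutes with rigid rotation at every rotation
  angle, so the talar angle is exactly rotation-equivariant. A tie at an
  exact 90° spread (never approached by talar anatomy) breaks toward the
  vertical. Exactly parallel tangents return their common direction.
* **Sign convention.** Internal rotation is negative, external positive.
  Right-sided slices keep the raw image angle; left-sided slices negate
  it, so mirror-image limbs yield identical anatomical values. The
  left/right-to-image mapping is a package convention (scanners and PACS
  viewers differ); callers with real data must confirm that image-right
  corresponds to the convention used here or mirror their input.
* **Degenerate inputs.** Fewer than 3 (circle) or 2 distinct (line)
  points, collinear circle input, and coincident malleolar centroids
  raise errors carrying the anatomical structure label; batch measurement
  converts per-tibia failures into reported exclusions rather than
  aborting the cohort.

## Synthetic cohorts

Because the reference study's raw tracings are not public, validation is
by simulation with known truth. Canonical 0° templates (plateau arcs of
radius 12/11 mm centered ±20 mm from the midline, margin at y = −14 mm,
malleolar centroids at ±25 mm, facet segments at ±15° about the sagittal
midline) are rotated to realize a truth triple (p, t, f):

* proximal slice rotated by p ⇒ PTTA = PMTPA = p exactly (the template
  makes the center line and posterior margin parallel by construction);
* talus and medial malleolus rotated by t ⇒ TA = t exactly;
* lateral malleolus rotated by t + 2f ⇒ the intermalleolar chord makes
  the angle t + f exactly, since both malleolar centroids lie at the same
  radius from the talar center and a chord's direction is the mean of its
  endpoints' arc positions.

f — the *fibular offset* — is the minimal mechanism for the recognised
positional variability of the distal fibula: it displaces the
intermalleolar axis without moving the talus, making IMA = TA + f. Under
independent normal truths this yields the closed form
corr(IMA, TA) = σ_t/√(σ_t² + σ_f²).

Left tibias are exact mirror images of the right-side construction.
Rater imprecision is isotropic Gaussian jitter on landmark coordinates
(per rater × session), so downstream reliability coefficients reflect
geometry-propagated error, as in a real protocol.

### Default conditions

| parameter | default | rationale |
|---|---|---|
| subjects (2 tibias each) | 100 | reference cohort size (200 tibias) |
| proximal truth | N(−7.6°, 14.2°²) | reference PMTPA mean/SD |
| talar truth | N(17.2°, 16.9°²) | reference TA mean/SD |
| fibular offset | N(5.8°, 4°²) | reported IMA−TA mean difference; SD set so corr(IMA, TA) ≈ 0.97, consistent with the reported 0.94 |
| landmark jitter | 0.5 mm | places simulated ICCs in the reported 0.92–0.999 range; no published noise magnitude exists, so this is a calibration, exposed as a parameter |
| raters × sessions | 2 × 2 | supports both reliability designs |
| proximal skew | 0 | optional skew-normal shape (mean/SD preserved) to exercise the non-normal reporting branch |

Truth draws are rejection-truncated at |angle| ≤ 88° (including the
implied IMA) so the (−90°, 90°] fold never wraps; at these SDs that
truncates ≈4σ tails and is statistically negligible.

### What the simulator does and does not emulate

It reproduces the *statistical structure* of a torsion cohort — truth
dispersion, inter-method correlation, a fibular-position offset, rater
noise propagated through geometry — not anatomy: bone contours are
circles and straight segments, slices are perfectly aligned with the bone
axis, and proximal and distal truths are drawn independently. The last
point matters when comparing composed torsion SDs: with independent
truths SD(TTA1) ≈ √(14.2² + 16.2²) ≈ 21.5°, whereas the reference cohort
reports 15.1°, implying a positive proximal–distal correlation in real
anatomy that the generator does not model. Passing tests therefore
demonstrate correctness of the measurement and statistics pipeline, not
anatomical realism.

## Statistics

* **Summaries** report n, missing, mean, median, SD, min, max per method;
  a Shapiro–Wilk gate at α = 0.05 selects the display rule (mean ± SD
  vs median [range]). Constant vectors are flagged degenerate.
* **Paired comparisons** dispatch on the normality of the paired
  differences: paired t when Shapiro–Wilk does not reject at 0.05,
  Wilcoxon signed-rank otherwise (zero differences dropped, the standard
  treatment). All-zero differences are reported as degenerate with p = 1
  and no statistic.
* **Correlation** is Pearson's r with a Fisher-z 95% interval
  (tanh(atanh r ± 1.96/√(n−3))).
* **ICC** is the single-measurement intraclass correlation from the
  two-way crossed ANOVA mean squares. The default form is two-way random
  effects, absolute agreement (the conservative choice for
  method-feasibility claims); two-way mixed, consistency is selectable.
  Confidence bounds use the standard F-distribution formulas for single
  measurements. Bands: poor < 0.5, moderate 0.5–0.75, good (0.75, 0.9],
  excellent > 0.9 — boundary values 0.5, 0.75 and 0.9 map to moderate,
  moderate and good respectively.
* **Reliability designs**: intra-observer uses one rater's two sessions
  on a 22-tibia subsample; inter-observer uses two raters' first sessions
  on 44 tibias. Whether a "scan image" in such designs means a tibia or a
  patient is ambiguous in the literature; the subsample is counted in
  tibias and the size is a parameter. Subsampling is deterministic from a
  seed.
* **No multiplicity adjustment** is applied; p-values are unadjusted, as
  is usual in single-protocol feasibility reports.
* The analysis unit is the tibia (two per subject); within-patient
  clustering of sides is not modeled. This mirrors common practice and is
  a documented limitation, not an oversight.

## Problem sizes

The test suite and the acceptance script run cohorts of 100 subjects
(200 tibias) for recovery and comparison checks, 22/44-tibia subsamples
for reliability, 100-replicate oracle sweeps for the geometric fits, and
4,000 null replicates per branch for type-I calibration — sizes chosen to
keep Monte-Carlo error well inside the asserted bands while completing in
seconds to a few minutes.

## Known limitations

* Conventions the source protocol leaves unstated (left/right image
  handedness, the horizontal reference, the bisector branch) are fixed
  here by explicit, testable rules; real-data users must verify their
  export matches them.
* The simulator's independence of proximal and distal truths inflates
  composed-torsion SDs relative to real cohorts (see above).
* No pixel-level image handling: landmarks must be produced upstream.
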