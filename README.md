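# tibtorsion

Measurement of **pediatric tibial torsion** from labeled landmarks on
axial CT slices, with a ground-truth simulator and the
reliability/method-comparison statistics needed to validate a
measurement protocol.

Tibial torsion — the axial rotation of the distal tibia relative to the
proximal tibia — is assessed on CT by drawing an axis on a proximal slice
(at the growth-plate level) and an axis on an ankle slice, each measured
against the image horizontal, and subtracting. This package implements
the four axis constructions in use for children:

| angle | axis |
|---|---|
| PTTA | line through the centers of circles fitted to the medial and lateral tibial-plateau arcs |
| PMTPA | total-least-squares line along the posterior plateau margin |
| IMA | line through the medial and lateral malleolar centroids |
| TA | perpendicular to the bisector of the tangents to the medial and lateral talar facets |

with the torsion compositions `TTA1 = IMA − PMTPA` and
`TTA2 = TA − PMTPA` (internal rotation negative, external positive; all
angles in degrees, folded into (−90°, 90°]). The talar angle frees the
distal measurement from the fibula's positional and ossification
variability, which systematically inflates IMA relative to TA.

Because raw clinical tracings are generally not shareable, the package
ships a **synthetic cohort generator**: each tibia is built from
canonical templates rotated to exact, known truth angles, with fibular
position modeled as an angular offset of the lateral malleolus and rater
imprecision as millimetre-scale jitter on landmark coordinates. Every
measure recovers its generating truth exactly in the noise-free limit,
which is what makes the pipeline testable end to end.

## Worked example

```python
from tibtorsion import CohortSpec, TorsionStudy, simulate_cohort

cohort = simulate_cohort(CohortSpec(n_subjects=30, seed=3))   # 60 tibias
results = TorsionStudy.from_cohort(cohort).fit()
print(results.summary())
```

prints (abridged):

```text
Angle distributions (degrees):
                     PTTA      PMTPA        IMA         TA
N                      60         60         60         60
Mean            -7.024228  -7.008623   24.18816  18.646727
SD              15.605917  15.658248  18.509153  18.441119
...
Paired method comparisons:
  PTTA_vs_PMTPA: paired-t, mean diff -0.016°, p = 0.914 (normality p = 0.138)
  IMA_vs_TA: wilcoxon-signed-rank, mean diff +5.541°, p = 5.7e-10 (normality p = 0.026)

Pearson correlations (Fisher-z 95% CI):
  PTTA_vs_PMTPA: r = 0.9975 [0.9957, 0.9985], p = 2.7e-68, n = 60
  IMA_vs_TA: r = 0.9743 [0.9571, 0.9846], p = 3.16e-39, n = 60

Intra-observer reliability (ICC):
  PTTA: ICC = 0.999 [0.998, 1.000] — excellent (22 tibias × 2 readings)
  ...
```

Reading this: the two proximal axis definitions agree (mean difference
−0.02°, not significant, r ≈ 1), while the two distal definitions differ
systematically — IMA exceeds TA by ≈ 5.5° (the simulated fibular offset
is 5.8°) with high correlation, and all four measures are in the
excellent reliability band under 0.5 mm rater noise. That is precisely
the pattern the underlying clinical question turns on: the *proximal*
axis choice is immaterial, the *distal* axis choice is not.

The same pipeline runs from the shell:

```sh
tibtorsion simulate --n 30 --seed 3 --out sim/
tibtorsion measure sim/landmarks.csv --out records.csv
tibtorsion stats records.csv --design compare --out report
tibtorsion stats records.csv --design intra --out reliability
```

Landmark files are plain CSV, one point per row
(`subject_id,side,slice,structure,point_index,x_mm,y_mm,rater,session`),
with a hierarchical JSON mirror; any upstream tool that exports labeled
points in this schema can feed `measure`.

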