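"""Synthetic landmark cohorts with known ground-truth angles.

Real torsion studies trace landmarks on CT slices by hand; no public
landmark dataset accompanies the reference cohort, so validation rests on
simulation. The generator builds each tibia from canonical 0° templates:

* a proximal slice whose plateau-circle center line and posterior margin
  are horizontal and parallel (so PTTA = PMTPA = 0 by construction);
* an ankle slice with malleolar centroids on the horizontal through the
  talar center and talar facets symmetric about the sagittal midline
  (IMA = TA = 0).

A tibia with true angles (p, t, f) — proximal angle, talar angle, fibular
offset — is realized by rotating the proximal slice by p, the talus and
medial malleolus by t, and the lateral malleolus by t + 2f about the talar
center; since both malleolar centroids sit at the same radius from that
center, the chord through them then makes exactly the angle t + f with the
horizontal, so the measured IMA equals t + f with zero error. Fibular
positional variability — the recognised driver of the IMA−TA discrepancy —
is thus a single angular offset of the lateral malleolus along its arc.

Left tibias are exact mirror images of the right-side construction, which
under the mirror sign convention yields identical anatomical angles.

Rater imprecision is modeled as isotropic Gaussian jitter on landmark
coordinates (mm), applied independently per rater × session, so that
downstream ICCs reflect geometry-propagated error rather than additive
angle noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import LandmarkSet
from .measures import TorsionRecord, measure_cohort
from .reference import REFERENCE_FIBULAR_OFFSET_MEAN, REFERENCE_SUMMARY

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "TrueAngles",
    "make_ankle_template",
    "make_proximal_template",
    "simulate_cohort",
    "synthesize_tibia",
]

#: truth draws are rejected beyond this bound so the (−90, 90] angle fold
#: never wraps; at reference-scale SDs this truncates ≈4σ tails only.
_TRUTH_BOUND_DEG = 88.0


@dataclass(frozen=True)
class TrueAngles:
    """Ground-truth angles (degrees) for one simulated tibia.

    ``proximal`` drives both proximal measures; ``distal_talar`` is the
    true talar angle; ``fibular_offset`` is the extra rotation of the
    intermalleolar axis contributed by fibular position, so the implied
    true IMA is ``distal_talar + fibular_offset``.
    """

    proximal: float
    distal_talar: float
    fibular_offset: float = 0.0

    def __post_init__(self):
        for name in ("proximal", "distal_talar"):
            v = getattr(self, name)
            if not -90.0 < v < 90.0:
                raise ValueError(f"{name}={v} outside (−90, 90)")
        if not -90.0 < self.true_ima < 90.0:
            raise ValueError(f"implied IMA {self.true_ima} outside (−90, 90)")

    @property
    def true_ima(self) -> float:
        return self.distal_talar + self.fibular_offset


@dataclass(frozen=True)
class CohortSpec:
    """Simulation conditions for a two-tibia-per-subject landmark cohort.

    Defaults reproduce the reference cohort's scale: 100 subjects (200
    tibias), proximal angles N(−7.6°, 14.2°²), talar angles
    N(17.2°, 16.9°²), fibular offset N(5.8°, 4°²), and 0.5 mm isotropic
    two-rater landmark jitter, which places simulated ICCs in the
    published excellent band. ``proximal_skew`` (skew-normal shape, mean
    and SD preserved) is 0 by default; set it nonzero to push the proximal
    angles into the non-normal reporting branch.
    """

    n_subjects: int = 100
    proximal_mean: float = REFERENCE_SUMMARY["PMTPA"]["mean"]
    proximal_sd: float = REFERENCE_SUMMARY["PMTPA"]["sd"]
    distal_mean: float = REFERENCE_SUMMARY["TA"]["mean"]
    distal_sd: float = REFERENCE_SUMMARY["TA"]["sd"]
    fibular_offset_mean: float = REFERENCE_FIBULAR_OFFSET_MEAN
    fibular_offset_sd: float = 4.0
    rater_noise_sd: float = 0.5
    raters: int = 2
    sessions: int = 2
    proximal_skew: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        for name in ("proximal_sd", "distal_sd", "fibular_offset_sd", "rater_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.raters < 1 or self.sessions < 1:
            raise ValueError("raters and sessions must be ≥ 1")


def _arc(center, radius, start_deg, stop_deg, n) -> np.ndarray:
    ang = np.deg2rad(np.linspace(start_deg, stop_deg, n))
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _segment(center, direction_deg, offsets) -> np.ndarray:
    rad = np.deg2rad(direction_deg)
    u = np.array([np.cos(rad), np.sin(rad)])
    return np.asarray(center, dtype=float) + np.outer(offsets, u)


#: cross-shaped malleolar point cloud whose centroid is exactly its center
_MALLEOLUS_OFFSETS = np.array([[-1.5, 0.0], [1.5, 0.0], [0.0, -1.0], [0.0, 1.0]])


def make_proximal_template(subject_id="template", side="right", rater="r1", session=1):
    """Canonical 0° proximal slice: PTTA = PMTPA = 0 by construction.

    Medial plateau arc on a circle of center (−20, 0) mm, radius 12 mm;
    lateral arc on center (20, 0), radius 11; posterior margin on the
    horizontal y = −14.
    """
    structures = {
        "medial_plateau": _arc((-20.0, 0.0), 12.0, 110.0, 250.0, 10),
        "lateral_plateau": _arc((20.0, 0.0), 11.0, -70.0, 70.0, 10),
        "posterior_margin": np.column_stack(
            [np.linspace(-15.0, 15.0, 6), np.full(6, -14.0)]
        ),
    }
    return LandmarkSet(subject_id, side, "proximal", structures, rater, session)


def make_ankle_template(subject_id="template", side="right", rater="r1", session=1):
    """Canonical 0° ankle slice: IMA = TA = 0 by construction.

    Malleolar centroids at (−25, 0) and (25, 0) mm; talar facets are
    near-sagittal segments at ±15° about vertical, symmetric about the
    midline, so the facet bisector is vertical and the talar axis
    horizontal.
    """
    structures = {
        "medial_malleolus": np.array([-25.0, 0.0]) + _MALLEOLUS_OFFSETS,
        "lateral_malleolus": np.array([25.0, 0.0]) + _MALLEOLUS_OFFSETS,
        "talus_medial_facet": _segment((-10.0, 0.0), 105.0, [-6.0, -2.0, 2.0, 6.0]),
        "talus_lateral_facet": _segment((10.0, 0.0), 75.0, [-6.0, -2.0, 2.0, 6.0]),
    }
    return LandmarkSet(subject_id, side, "ankle", structures, rater, session)


def _rot(deg: float) -> np.ndarray:
    rad = np.deg2rad(deg)
    return np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])


def synthesize_tibia(
    truth: TrueAngles,
    side: str = "right",
    subject_id: str = "synthetic",
    rater: str = "r1",
    session: int = 1,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Noise-free (proximal, ankle) landmark sets realizing ``truth`` exactly.

    The lateral malleolus rotates by ``distal_talar + 2·fibular_offset``:
    the intermalleolar chord angle is the mean of the two malleolar arc
    positions, so the measured IMA lands on ``distal_talar +
    fibular_offset`` with zero error.
    """
    prox = make_proximal_template(subject_id, "right", rater, session)
    prox = prox.transformed(lambda pts: pts @ _rot(truth.proximal).T)

    ankle_t = make_ankle_template(subject_id, "right", rater, session)
    r_talus = _rot(truth.distal_talar)
    r_fib = _rot(truth.distal_talar + 2.0 * truth.fibular_offset)
    structures = {
        label: pts @ (r_fib if label == "lateral_malleolus" else r_talus).T
        for label, pts in ankle_t.structures.items()
    }
    ankle = LandmarkSet(subject_id, "right", "ankle", structures, rater, session)

    if side == "left":
        prox = prox.mirrored(about_x=0.0, swap_side=True)
        ankle = ankle.mirrored(about_x=0.0, swap_side=True)
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return prox, ankle


@dataclass
class CohortTruth:
    """A realized cohort: truth table plus per-rater/session landmark sets."""

    spec: CohortSpec
    truth: pd.DataFrame  # one row per tibia
    landmarks: list[LandmarkSet] = field(repr=False, default_factory=list)

    @property
    def n_tibias(self) -> int:
        return len(self.truth)

    def landmarks_for(self, rater: str | None = None, session: int | None = None):
        out = self.landmarks
        if rater is not None:
            out = [lm for lm in out if lm.rater == rater]
        if session is not None:
            out = [lm for lm in out if lm.session == session]
        return out

    def measure(
        self, rater: str | None = None, session: int | None = None
    ) -> tuple[list[TorsionRecord], list[dict]]:
        """Run the measurement pipeline on (a subset of) the landmark files."""
        return measure_cohort(self.landmarks_for(rater, session))


def _draw_truncated(draw, bound=_TRUTH_BOUND_DEG, max_tries=1000):
    for _ in range(max_tries):
        v = draw()
        if abs(v) <= bound:
            return v
    raise RuntimeError("truth rejection sampling failed; check spec parameters")


def _proximal_sampler(spec: CohortSpec, rng: np.random.Generator):
    """Mean/SD-preserving proximal draw, skew-normal when proximal_skew ≠ 0."""
    if spec.proximal_skew == 0.0:
        return lambda: rng.normal(spec.proximal_mean, spec.proximal_sd)
    a = spec.proximal_skew
    delta = a / np.sqrt(1.0 + a * a)
    mu_z = delta * np.sqrt(2.0 / np.pi)
    sd_z = np.sqrt(1.0 - mu_z * mu_z)

    def draw():
        z = stats.skewnorm.rvs(a, random_state=rng)
        return spec.proximal_mean + spec.proximal_sd * (z - mu_z) / sd_z

    return draw


def simulate_cohort(spec: CohortSpec) -> CohortTruth:
    """Draw per-tibia truths and emit jittered landmark sets per rater × session.

    Fully reproducible: identical spec (including seed) gives identical
    truth tables and byte-identical landmark coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    draw_prox = _proximal_sampler(spec, rng)

    rows = []
    for i in range(spec.n_subjects):
        subject = f"s{i + 1:04d}"
        for side in ("left", "right"):
            p = _draw_truncated(draw_prox)
            while True:
                t = rng.normal(spec.distal_mean, spec.distal_sd)
                f = rng.normal(spec.fibular_offset_mean, spec.fibular_offset_sd)
                if abs(t) <= _TRUTH_BOUND_DEG and abs(t + f) <= _TRUTH_BOUND_DEG:
                    break
            rows.append(
                {
                    "subject_id": subject,
                    "side": side,
                    "proximal": p,
                    "distal_talar": t,
                    "fibular_offset": f,
                    "true_ima": t + f,
                }
            )
    truth = pd.DataFrame(rows)

    landmarks: list[LandmarkSet] = []
    for r in range(spec.raters):
        rater = f"r{r + 1}"
        for session in range(1, spec.sessions + 1):
            for row in rows:
                pair = synthesize_tibia(
                    TrueAngles(row["proximal"], row["distal_talar"], row["fibular_offset"]),
                    side=row["side"],
                    subject_id=row["subject_id"],
                    rater=rater,
                    session=session,
                )
                for lm in pair:
                    if spec.rater_noise_sd > 0:
                        lm = lm.transformed(
                            lambda pts: pts
                            + rng.normal(0.0, spec.rater_noise_sd, size=pts.shape)
                        )
                    landmarks.append(lm)
    return CohortTruth(spec=spec, truth=truth, landmarks=landmarks)
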