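"""The four named torsion angles and their composition into torsion values.

Per tibia, four angles to the image horizontal are measured:

* **PTTA** (proximal transtibial angle) — axis through the centers of the
  least-squares circles fitted to the medial and lateral plateau arcs;
* **PMTPA** (posterior margin tibial plateau angle) — total-least-squares
  line along the posterior plateau margin;
* **IMA** (intermalleolar angle) — axis through the centroids of the
  medial and lateral malleolar point clouds;
* **TA** (talar angle) — perpendicular to the bisector of the tangents to
  the medial and lateral talar facets.

Tibial torsion is then distal minus proximal (external torsion positive):
TTA1 = IMA − PMTPA and TTA2 = TA − PMTPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .geometry import (
    Axis,
    DegenerateGeometryError,
    anatomical_sign,
    bisector_direction,
    fit_circle,
    fit_line,
    perpendicular,
    raw_angle_to_horizontal,
)
from .landmarks import LandmarkSet

__all__ = [
    "METHODS",
    "AngleMeasurement",
    "TorsionRecord",
    "compute_torsion",
    "measure_ankle",
    "measure_cohort",
    "measure_ima",
    "measure_pmtpa",
    "measure_proximal",
    "measure_ptta",
    "measure_ta",
    "measurements_to_frame",
]

log = logging.getLogger(__name__)

METHODS = ("PTTA", "PMTPA", "IMA", "TA")


@dataclass(frozen=True)
class AngleMeasurement:
    """One signed anatomical angle (degrees) with its provenance."""

    method: str
    value: float
    subject_id: str
    side: str
    rater: str = "r1"
    session: int = 1

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not -90.0 < self.value <= 90.0:
            raise ValueError(f"angle {self.value} outside (−90, 90]")


@dataclass(frozen=True)
class TorsionRecord:
    """Per-tibia angle panel; tta1 = ima − pmtpa, tta2 = ta − pmtpa, exactly."""

    subject_id: str
    side: str
    ptta: float
    pmtpa: float
    ima: float
    ta: float
    tta1: float
    tta2: float
    rater: str = "r1"
    session: int = 1

    @classmethod
    def from_angles(
        cls, subject_id, side, ptta, pmtpa, ima, ta, rater="r1", session=1
    ) -> "TorsionRecord":
        return cls(
            subject_id=subject_id,
            side=side,
            ptta=ptta,
            pmtpa=pmtpa,
            ima=ima,
            ta=ta,
            tta1=ima - pmtpa,
            tta2=ta - pmtpa,
            rater=rater,
            session=session,
        )


def _require_slice(lm: LandmarkSet, slice_name: str) -> None:
    if lm.slice_name != slice_name:
        raise ValueError(
            f"expected a {slice_name!r} slice, got {lm.slice_name!r} "
            f"({lm.subject_id}/{lm.side})"
        )


def _signed(lm: LandmarkSet, method: str, axis: Axis) -> AngleMeasurement:
    value = anatomical_sign(raw_angle_to_horizontal(axis), lm.side)
    return AngleMeasurement(
        method=method,
        value=value,
        subject_id=lm.subject_id,
        side=lm.side,
        rater=lm.rater,
        session=lm.session,
    )


def measure_ptta(lm: LandmarkSet) -> AngleMeasurement:
    """Angle of the axis through the two fitted plateau-circle centers."""
    _require_slice(lm, "proximal")
    medial = fit_circle(lm.structures["medial_plateau"], "medial_plateau")
    lateral = fit_circle(lm.structures["lateral_plateau"], "lateral_plateau")
    axis = Axis.through(medial.center, lateral.center)
    return _signed(lm, "PTTA", axis)


def measure_pmtpa(lm: LandmarkSet) -> AngleMeasurement:
    """Angle of the posterior plateau-margin line."""
    _require_slice(lm, "proximal")
    axis = fit_line(lm.structures["posterior_margin"], "posterior_margin")
    return _signed(lm, "PMTPA", axis)


def measure_ima(lm: LandmarkSet) -> AngleMeasurement:
    """Angle of the central line through the two malleolar centroids."""
    _require_slice(lm, "ankle")
    med = lm.structures["medial_malleolus"].mean(axis=0)
    lat = lm.structures["lateral_malleolus"].mean(axis=0)
    if abs(med[0] - lat[0]) < 1e-9 and abs(med[1] - lat[1]) < 1e-9:
        raise DegenerateGeometryError(
            "malleolar centroids coincide; intermalleolar axis undefined",
            "lateral_malleolus",
        )
    return _signed(lm, "IMA", Axis.through(tuple(med), tuple(lat)))


def measure_ta(lm: LandmarkSet) -> AngleMeasurement:
    """Talar angle: tangents to both facets → bisector → perpendicular."""
    _require_slice(lm, "ankle")
    medial = fit_line(lm.structures["talus_medial_facet"], "talus_medial_facet")
    lateral = fit_line(lm.structures["talus_lateral_facet"], "talus_lateral_facet")
    talar = perpendicular(bisector_direction(medial, lateral))
    axis = Axis(anchor=medial.anchor, direction=talar)
    return _signed(lm, "TA", axis)


def measure_proximal(lm: LandmarkSet) -> tuple[AngleMeasurement, AngleMeasurement]:
    return measure_ptta(lm), measure_pmtpa(lm)


def measure_ankle(lm: LandmarkSet) -> tuple[AngleMeasurement, AngleMeasurement]:
    return measure_ima(lm), measure_ta(lm)


def compute_torsion(proximal: AngleMeasurement, distal: AngleMeasurement) -> float:
    """Torsion = distal − proximal (degrees, external torsion positive)."""
    if proximal.method not in ("PMTPA", "PTTA"):
        raise ValueError(f"proximal measurement expected, got {proximal.method}")
    if distal.method not in ("IMA", "TA"):
        raise ValueError(f"distal measurement expected, got {distal.method}")
    if (proximal.subject_id, proximal.side) != (distal.subject_id, distal.side):
        raise ValueError(
            "pairing error: proximal "
            f"{(proximal.subject_id, proximal.side)} vs distal "
            f"{(distal.subject_id, distal.side)}"
        )
    return distal.value - proximal.value


def measure_cohort(
    landmark_sets: Iterable[LandmarkSet],
) -> tuple[list[TorsionRecord], list[dict]]:
    """Measure every tibia that has both slices; collect per-tibia failures.

    Returns ``(records, exclusions)`` where each exclusion is a dict with
    the tibia key and the reason. Output is deterministically ordered by
    (subject_id, side, rater, session).
    """
    grouped: dict[tuple, dict[str, LandmarkSet]] = {}
    for lm in landmark_sets:
        slot = grouped.setdefault(lm.key, {})
        if lm.slice_name in slot:
            raise ValueError(f"duplicate {lm.slice_name} slice for tibia {lm.key}")
        slot[lm.slice_name] = lm

    records: list[TorsionRecord] = []
    exclusions: list[dict] = []
    for key in sorted(grouped):
        subject_id, side, rater, session = key
        slices = grouped[key]
        try:
            if "proximal" not in slices or "ankle" not in slices:
                missing = sorted({"proximal", "ankle"} - set(slices))
                raise ValueError(f"missing slice(s): {missing}")
            ptta, pmtpa = measure_proximal(slices["proximal"])
            ima, ta = measure_ankle(slices["ankle"])
            records.append(
                TorsionRecord.from_angles(
                    subject_id,
                    side,
                    ptta.value,
                    pmtpa.value,
                    ima.value,
                    ta.value,
                    rater=rater,
                    session=session,
                )
            )
        except (ValueError, DegenerateGeometryError) as exc:
            log.warning("excluding tibia %s: %s", key, exc)
            exclusions.append(
                {
                    "subject_id": subject_id,
                    "side": side,
                    "rater": rater,
                    "session": session,
                    "reason": str(exc),
                }
            )
    return records, exclusions


def measurements_to_frame(records: Iterable[TorsionRecord]) -> pd.DataFrame:
    """Long-format angle table: one row per (tibia, rater, session, method)."""
    rows = []
    for r in records:
        for method, value in (
            ("PTTA", r.ptta),
            ("PMTPA", r.pmtpa),
            ("IMA", r.ima),
            ("TA", r.ta),
        ):
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "side": r.side,
                    "rater": r.rater,
                    "session": r.session,
                    "method": method,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
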