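"""Labeled landmark sets for the two measurement slices of one tibia.

A torsion study traces points on exactly two axial CT sections per tibia:

* ``proximal`` — at the level of the growth plate: the medial and lateral
  tibial-plateau arcs (≥3 points each, for circle fits) and the posterior
  plateau margin (≥2 points, for a line fit);
* ``ankle`` — the first section through the talar body, distal fibular
  epiphysis and medial malleolus: the two malleolar point clouds and the
  medial/lateral talar facet tracings (≥2 points each).

Structure labels are a controlled vocabulary; anything else is rejected at
construction so file-format errors surface with the offending label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SIDES, _as_points

__all__ = [
    "ANKLE_STRUCTURES",
    "PROXIMAL_STRUCTURES",
    "SLICES",
    "LandmarkSet",
    "LandmarkValidationError",
]

SLICES = ("proximal", "ankle")

#: required structure label → minimum point count
PROXIMAL_STRUCTURES: dict[str, int] = {
    "medial_plateau": 3,
    "lateral_plateau": 3,
    "posterior_margin": 2,
}
ANKLE_STRUCTURES: dict[str, int] = {
    "medial_malleolus": 1,
    "lateral_malleolus": 1,
    "talus_medial_facet": 2,
    "talus_lateral_facet": 2,
}


class LandmarkValidationError(ValueError):
    """A landmark set violates the slice schema (labels, counts, coordinates)."""


def _required(slice_name: str) -> dict[str, int]:
    if slice_name == "proximal":
        return PROXIMAL_STRUCTURES
    if slice_name == "ankle":
        return ANKLE_STRUCTURES
    raise LandmarkValidationError(
        f"unknown slice {slice_name!r}; expected one of {SLICES}"
    )


@dataclass
class LandmarkSet:
    """All tracings for one slice of one tibia by one rater in one session.

    ``structures`` maps structure label → (n, 2) float array of points in
    millimetres (x image-right, y anterior).
    """

    subject_id: str
    side: str
    slice_name: str
    structures: dict[str, np.ndarray]
    rater: str = "r1"
    session: int = 1

    key: tuple = field(init=False, repr=False)

    def __post_init__(self):
        if self.side not in SIDES:
            raise LandmarkValidationError(
                f"side must be one of {SIDES}, got {self.side!r}"
            )
        required = _required(self.slice_name)
        unknown = set(self.structures) - set(required)
        if unknown:
            raise LandmarkValidationError(
                f"unknown structure label(s) {sorted(unknown)} for "
                f"{self.slice_name!r} slice (allowed: {sorted(required)})"
            )
        missing = set(required) - set(self.structures)
        if missing:
            raise LandmarkValidationError(
                f"missing structure(s) {sorted(missing)} for "
                f"{self.slice_name!r} slice of {self.subject_id}/{self.side}"
            )
        clean: dict[str, np.ndarray] = {}
        for label, pts in self.structures.items():
            arr = _as_points(pts)
            if len(arr) < required[label]:
                raise LandmarkValidationError(
                    f"{label}: needs ≥{required[label]} points, got {len(arr)}"
                )
            clean[label] = arr
        self.structures = clean
        self.key = (self.subject_id, self.side, self.rater, int(self.session))

    def transformed(self, fn) -> "LandmarkSet":
        """New LandmarkSet with ``fn`` applied to every (n, 2) point array."""
        return LandmarkSet(
            subject_id=self.subject_id,
            side=self.side,
            slice_name=self.slice_name,
            structures={k: fn(v) for k, v in self.structures.items()},
            rater=self.rater,
            session=self.session,
        )

    def mirrored(self, about_x: float = 0.0, swap_side: bool = True) -> "LandmarkSet":
        """Reflect about the vertical line x = ``about_x``; optionally swap side."""
        out = self.transformed(
            lambda pts: np.column_stack([2.0 * about_x - pts[:, 0], pts[:, 1]])
        )
        if swap_side:
            out = LandmarkSet(
                subject_id=out.subject_id,
                side="left" if self.side == "right" else "right",
                slice_name=out.slice_name,
                structures=out.structures,
                rater=out.rater,
                session=out.session,
            )
        return out
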