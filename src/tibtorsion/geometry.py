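"""2D geometric primitives for axial-slice torsion measurement.

Every axis drawn in a CT torsion measurement — transtibial center line,
posterior plateau margin, intermalleolar line, talar facet tangents and
their bisector — reduces to a handful of primitives on labeled 2D points:
least-squares circles, total-least-squares lines, axis bisectors and
perpendiculars, and signed angles to the image horizontal.

Coordinate convention: x increases to image-right, y increases anteriorly,
units are millimetres. An :class:`Axis` is undirected — a direction ``d``
and ``-d`` name the same axis, so every angle here lives modulo 180° and is
folded into the half-open interval (−90°, 90°].

The anatomical sign convention follows clinical usage: an internally
rotated axis carries a negative angle, an externally rotated one positive.
Left-sided slices are treated as mirror images of right-sided ones, so the
two limbs of one patient yield directly comparable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Axis",
    "CircleFit",
    "DegenerateGeometryError",
    "anatomical_sign",
    "axis_angle",
    "bisector_direction",
    "fit_circle",
    "fit_line",
    "fold_axis_angle",
    "perpendicular",
    "raw_angle_to_horizontal",
    "rotate_points",
]

SIDES = ("left", "right")

#: numerical tolerance for "exactly parallel" axes, in degrees
_PARALLEL_TOL_DEG = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when a point set cannot support the requested construction.

    Carries the anatomical structure label (when known) so batch callers
    can report which tracing was at fault.
    """

    def __init__(self, message: str, structure: str | None = None):
        self.structure = structure
        if structure is not None:
            message = f"{structure}: {message}"
        super().__init__(message)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmark coordinates must be finite")
    return pts


def fold_axis_angle(deg: float) -> float:
    """Fold an angle in degrees into the axis range (−90, 90]."""
    folded = (float(deg) + 90.0) % 180.0 - 90.0
    if folded == -90.0:
        folded = 90.0
    return folded


def _upper_half_unit(direction: np.ndarray) -> np.ndarray:
    """Canonical unit representative of an undirected direction (dy ≥ 0)."""
    d = np.asarray(direction, dtype=float)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0:
        raise ValueError("zero direction vector")
    d = d / norm
    if d[1] < 0.0 or (d[1] == 0.0 and d[0] < 0.0):
        d = -d
    return d


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: center (mm), radius (mm), RMS radial residual."""

    center: tuple[float, float]
    radius: float
    rms_residual: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


@dataclass(frozen=True)
class Axis:
    """An undirected 2D line through ``anchor`` with unit ``direction``.

    ``Axis(p, d)`` and ``Axis(p, -d)`` compare as the same axis; the stored
    direction is normalised to the upper half-plane representative.
    """

    anchor: tuple[float, float]
    direction: tuple[float, float] = field(default=(1.0, 0.0))

    def __post_init__(self):
        d = _upper_half_unit(np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "direction", (float(d[0]), float(d[1])))
        object.__setattr__(
            self, "anchor", (float(self.anchor[0]), float(self.anchor[1]))
        )

    @classmethod
    def through(cls, p: tuple[float, float], q: tuple[float, float]) -> "Axis":
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        return cls(anchor=tuple(p), direction=tuple(q - p))

    @classmethod
    def from_angle(cls, deg: float, anchor=(0.0, 0.0)) -> "Axis":
        rad = np.deg2rad(deg)
        return cls(anchor=tuple(anchor), direction=(np.cos(rad), np.sin(rad)))


def axis_angle(direction) -> float:
    """Angle of an undirected direction from +x, folded into (−90, 90]."""
    d = np.asarray(direction, dtype=float)
    return fold_axis_angle(np.degrees(np.arctan2(d[1], d[0])))


def fit_circle(points, structure: str | None = None) -> CircleFit:
    """Geometric least-squares circle through ≥3 non-collinear points.

    The algebraic (Kåsa) solution of 2ax + 2by + c = x² + y² provides the
    closed-form start; Gauss–Newton iterations on the true radial
    residuals |pᵢ − center| − r then remove the algebraic fit's partial-arc
    bias, which on short plateau arcs with placement noise can reach
    tenths of a millimetre. Exact (zero residual, no iteration needed)
    whenever the points lie on one circle; fully deterministic.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError(
            f"circle fit needs at least 3 points, got {n}", structure
        )
    centered = pts - pts.mean(axis=0)
    # collinearity check via the scatter spectrum, scale-relative
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] / sv[0] < 1e-9:
        raise DegenerateGeometryError(
            "points are collinear; cannot fit a circle", structure
        )
    A = np.column_stack([2.0 * pts[:, 0], 2.0 * pts[:, 1], np.ones(n)])
    b = (pts**2).sum(axis=1)
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    radius = float(np.sqrt(c + cx * cx + cy * cy))

    center = np.array([cx, cy])
    r = radius
    for _ in range(50):
        delta = pts - center
        dist = np.hypot(delta[:, 0], delta[:, 1])
        if np.any(dist < 1e-12):  # a landmark at the center: keep current fit
            break
        resid = dist - r
        jac = np.column_stack([-delta[:, 0] / dist, -delta[:, 1] / dist, -np.ones(n)])
        step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
        center = center + step[:2]
        r = float(r + step[2])
        if np.abs(step).sum() < 1e-12:
            break
    if not np.isfinite(r) or r <= 0:  # refinement diverged: algebraic fallback
        center, r = np.array([cx, cy]), radius

    dists = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rms = float(np.sqrt(np.mean((dists - r) ** 2)))
    return CircleFit(center=(float(center[0]), float(center[1])), radius=float(r),
                     rms_residual=rms)


def fit_line(points, structure: str | None = None) -> Axis:
    """Total-least-squares line: first principal direction through the centroid.

    Orthogonal (not ordinary) regression, so near-vertical tracings — talar
    facets, a steep plateau margin — are fitted without bias.
    """
    pts = _as_points(points)
    if len(np.unique(pts, axis=0)) < 2:
        raise DegenerateGeometryError(
            "line fit needs at least 2 distinct points", structure
        )
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    return Axis(anchor=tuple(centroid), direction=tuple(vt[0]))


def _axis_distance_deg(a: float, b: float) -> float:
    """Unsigned angular distance between two axes, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def bisector_direction(a: Axis, b: Axis) -> tuple[float, float]:
    """Bisector of the acute angle between two axes.

    Two bisectors exist, 90° apart. The talar facet tangents run
    near-parallel (near-sagittal on an unrotated slice), and the
    anatomically meaningful bisector — the anteroposterior talar midline —
    is the one inside the acute angle they form. Choosing it, rather than
    e.g. the bisector closer to vertical, keeps the construction
    rotation-equivariant at every rotation. Exactly parallel inputs return
    their common direction; at an exact 90° spread the tie breaks toward
    the branch closer to vertical.
    """
    t1 = axis_angle(a.direction)
    t2 = axis_angle(b.direction)
    # signed axis difference folded into (−90, 90]
    diff = fold_axis_angle(t2 - t1)
    if abs(diff) < _PARALLEL_TOL_DEG:
        return a.direction
    mid = t1 + diff / 2.0  # bisector of the acute angle between the lines
    if diff == 90.0:  # perpendicular inputs: both bisectors equally acute
        alt = mid + 90.0
        mid = mid if _axis_distance_deg(mid, 90.0) <= _axis_distance_deg(alt, 90.0) else alt
    rad = np.deg2rad(mid)
    d = _upper_half_unit(np.array([np.cos(rad), np.sin(rad)]))
    return (float(d[0]), float(d[1]))


def perpendicular(direction) -> tuple[float, float]:
    """90° counterclockwise rotation, as the upper-half-plane representative."""
    d = np.asarray(direction, dtype=float)
    norm = float(np.hypot(d[0], d[1]))
    if not np.isclose(norm, 1.0, atol=1e-9):
        raise ValueError("perpendicular() expects a unit direction")
    out = _upper_half_unit(np.array([-d[1], d[0]]))
    return (float(out[0]), float(out[1]))


def raw_angle_to_horizontal(a: Axis) -> float:
    """Counterclockwise angle from the image horizontal to the axis, (−90, 90]."""
    return axis_angle(a.direction)


def anatomical_sign(raw_angle: float, side: str) -> float:
    """Signed anatomical angle: internal rotation negative, external positive.

    Right-sided slices keep the raw image angle; left-sided slices negate
    it, so mirror-image limbs yield identical anatomical values and both
    limbs of one patient are directly comparable.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    if not -90.0 < raw_angle <= 90.0:
        raise ValueError(f"raw angle {raw_angle} outside (−90, 90]")
    return raw_angle if side == "right" else fold_axis_angle(-raw_angle)


def rotate_points(points, deg: float, center=(0.0, 0.0)) -> np.ndarray:
    """Rigidly rotate points by ``deg`` counterclockwise about ``center``."""
    pts = _as_points(points)
    c = np.asarray(center, dtype=float)
    rad = np.deg2rad(deg)
    rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    return (pts - c) @ rot.T + c
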