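"""Independent oracles used to cross-check the implementation.

Each oracle takes a deliberately different computational route from the
code under test: geometric (iterative) circle fitting vs the algebraic
closed form, eigen-decomposition of the scatter matrix vs SVD line
fitting, and loop-written two-way ANOVA mean squares vs the vectorized
ICC path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def geometric_circle_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Newton-type least-squares circle minimizing true radial residuals.

    Starts from the centroid and mean radius; returns (center, radius).
    """
    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    r0 = np.mean(np.hypot(*(pts - c0).T))

    def residuals(params):
        cx, cy, r = params
        return np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r

    sol = least_squares(residuals, x0=[c0[0], c0[1], r0], method="lm")
    return sol.x[:2], float(sol.x[2])


def eigen_line_direction(points: np.ndarray) -> float:
    """Principal direction of the 2×2 scatter matrix, as an axis angle in degrees."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    scatter = centered.T @ centered
    vals, vecs = np.linalg.eigh(scatter)
    d = vecs[:, np.argmax(vals)]
    ang = np.degrees(np.arctan2(d[1], d[0]))
    ang = (ang + 90.0) % 180.0 - 90.0
    return 90.0 if ang == -90.0 else ang


def anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed ANOVA, written with explicit loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (x[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc_oracle(x: np.ndarray, model: str) -> float:
    """Single-measurement ICC point estimate from the loop-written ANOVA."""
    n, k = np.asarray(x).shape
    msr, msc, mse = anova_mean_squares(x)
    if model == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    if model == "absolute":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    raise ValueError(model)


def pearson_oracle(a, b) -> float:
    """Textbook product-moment formula, written out."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
    den = np.sqrt(n * np.sum(a * a) - np.sum(a) ** 2) * np.sqrt(
        n * np.sum(b * b) - np.sum(b) ** 2
    )
    return float(num / den)


def upper_half_angle_mean(deg1: float, deg2: float) -> float:
    """Bisector oracle for near-sagittal axes: orient both directions into
    the upper half-plane and average the angles."""
    a1 = deg1 % 180.0
    a2 = deg2 % 180.0
    return (a1 + a2) / 2.0
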