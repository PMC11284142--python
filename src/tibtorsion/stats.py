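"""Reliability and method-comparison statistics for torsion measurements.

Implements the statistical pipeline a measurement-feasibility study runs
on a cohort of paired angle readings:

* normality-gated distribution summaries (mean ± SD when Shapiro–Wilk does
  not reject at α = 0.05, median [range] otherwise);
* paired method comparisons, dispatching between the paired t-test and the
  Wilcoxon signed-rank test on the normality of the paired differences;
* Pearson correlation with a Fisher-z 95% confidence interval;
* single-measurement intraclass correlation coefficients from the two-way
  ANOVA decomposition (random-effects/absolute-agreement by default,
  mixed/consistency selectable), with F-distribution confidence bounds and
  the conventional reliability bands: poor < 0.5 ≤ moderate ≤ 0.75 < good
  ≤ 0.9 < excellent.

No multiplicity adjustment is applied; p-values are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measures import METHODS, measurements_to_frame

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "InsufficientDataError",
    "PairedTestResult",
    "SummaryRow",
    "UndefinedCorrelationError",
    "fisher_ci",
    "icc",
    "icc_band",
    "paired_compare",
    "pearson_with_ci",
    "ratings_matrix",
    "reliability_study",
    "summarize",
]

NORMALITY_ALPHA = 0.05

ICC_MODELS = ("two-way-random-absolute", "two-way-mixed-consistency")
_MODEL_ALIASES = {
    "absolute": "two-way-random-absolute",
    "consistency": "two-way-mixed-consistency",
}


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class SummaryRow:
    """Distribution summary for one method, with its reporting rule."""

    method: str
    n: int
    missing: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    normality_p: float
    display: str  # "mean_sd" | "median_range" | "degenerate"


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str  # "paired-t" | "wilcoxon-signed-rank" | "degenerate"
    statistic: float
    p_value: float
    mean_difference: float
    normality_p: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    band: str
    n_subjects: int
    n_raters: int


def summarize(values, method: str = "", alpha: float = NORMALITY_ALPHA) -> SummaryRow:
    """Full summary row plus the mean±SD vs median[range] display rule."""
    arr = np.asarray(values, dtype=float).ravel()
    missing = int(np.sum(~np.isfinite(arr)))
    arr = arr[np.isfinite(arr)]
    if len(arr) < 3:
        raise InsufficientDataError(
            f"{method or 'summarize'}: needs ≥3 finite values, got {len(arr)}"
        )
    if np.ptp(arr) == 0.0:
        normality_p, display = float("nan"), "degenerate"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # large-n Shapiro accuracy warning
            normality_p = float(sps.shapiro(arr).pvalue)
        display = "mean_sd" if normality_p > alpha else "median_range"
    return SummaryRow(
        method=method,
        n=len(arr),
        missing=missing,
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        sd=float(np.std(arr, ddof=1)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        normality_p=normality_p,
        display=display,
    )


def paired_compare(a, b, alpha: float = NORMALITY_ALPHA) -> PairedTestResult:
    """Paired comparison of two matched reading series.

    The paired t-test is used when Shapiro–Wilk does not reject normality
    of the differences at ``alpha``; otherwise the Wilcoxon signed-rank
    test (zero differences dropped). All-zero differences are a degenerate
    case: reported with p = 1 and no test statistic.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"paired series differ in length: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise InsufficientDataError("paired comparison needs ≥3 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired comparison requires finite values")
    diffs = a - b
    mean_diff = float(np.mean(diffs))
    if np.all(diffs == 0.0):
        return PairedTestResult(
            "degenerate", float("nan"), 1.0, 0.0, float("nan"), len(a)
        )
    if np.ptp(diffs) == 0.0:  # constant nonzero shift: trivially non-normal-safe
        normality_p = float("nan")
        normal = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(sps.shapiro(diffs).pvalue)
        normal = normality_p > alpha
    if normal:
        res = sps.ttest_rel(a, b)
        return PairedTestResult(
            "paired-t", float(res.statistic), float(res.pvalue),
            mean_diff, normality_p, len(a),
        )
    res = sps.wilcoxon(diffs, zero_method="wilcox")
    return PairedTestResult(
        "wilcoxon-signed-rank", float(res.statistic), float(res.pvalue),
        mean_diff, normality_p, len(a),
    )


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise InsufficientDataError("Fisher-z interval needs n ≥ 4")
    if abs(r) >= 1.0:
        return (float(r), float(r))
    z = np.arctanh(r)
    half = sps.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_with_ci(a, b, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with Fisher-z CI and two-sided p."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("correlation inputs differ in length")
    if len(a) < 4:
        raise InsufficientDataError("correlation needs n ≥ 4")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedCorrelationError("zero variance input; correlation undefined")
    res = sps.pearsonr(a, b)
    lo, hi = fisher_ci(float(res.statistic), len(a), alpha)
    return CorrelationResult(
        r=float(res.statistic), ci_low=lo, ci_high=hi,
        p_value=float(res.pvalue), n=len(a),
    )


def icc_band(estimate: float) -> str:
    """Conventional reliability bands for an ICC estimate."""
    if estimate < 0.5:
        return "poor"
    if estimate <= 0.75:
        return "moderate"
    if estimate <= 0.9:
        return "good"
    return "excellent"


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way crossed ANOVA without replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(
    ratings, model: str = "two-way-random-absolute", alpha: float = 0.05
) -> ICCResult:
    """Single-measurement ICC from the two-way ANOVA decomposition.

    ``ratings`` is a complete subjects × raters (or sessions) matrix.
    ``model`` selects absolute agreement under two-way random effects
    (default; the conservative choice for method-feasibility claims) or
    consistency under two-way mixed effects. Confidence bounds use the
    standard F-distribution formulas for single measurements.
    """
    model = _MODEL_ALIASES.get(model, model)
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS} (or a short alias)")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects × raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise InsufficientDataError(
            f"ICC needs ≥5 subjects and ≥2 raters, got {n}×{k}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix contains missing or non-finite cells")

    msr, msc, mse = _mean_squares(x)

    if mse == 0.0 and (model == "two-way-mixed-consistency" or msc == 0.0):
        # perfect agreement (up to a rater shift, for the consistency form)
        est = 1.0 if msr > 0 else float("nan")
        return ICCResult(est, est, est, model, icc_band(est), n, k)

    if model == "two-way-mixed-consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        a = k * est / (n * (1 - est)) if est < 1 else float("inf")
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else float("inf")
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )

    lo = float(np.clip(lo, -1.0, est))
    hi = float(np.clip(hi, est, 1.0))
    return ICCResult(float(est), lo, hi, model, icc_band(float(est)), n, k)


def ratings_matrix(
    frame: pd.DataFrame,
    method: str,
    columns: Iterable[tuple[str, int]],
    tibias: Iterable[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Assemble a tibias × readings matrix from the long-format angle table.

    ``columns`` lists (rater, session) pairs; rows are (subject_id, side)
    tibias, sorted. Tibias missing any requested reading are an error.
    """
    sub = frame[frame["method"] == method]
    wide = sub.pivot_table(
        index=["subject_id", "side"],
        columns=["rater", "session"],
        values="value",
        aggfunc="first",
    )
    cols = [(r, int(s)) for r, s in columns]
    for c in cols:
        if c not in wide.columns:
            raise ValueError(f"no readings for rater/session {c} and method {method}")
    wide = wide[cols]
    if tibias is not None:
        wide = wide.loc[sorted(tibias)]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing readings for tibias {bad[:5]} (method {method})")
    return wide.sort_index().to_numpy()


def _angle_frame(cohort_or_frame) -> pd.DataFrame:
    if isinstance(cohort_or_frame, pd.DataFrame):
        return cohort_or_frame
    records, _ = cohort_or_frame.measure()
    return measurements_to_frame(records)


def reliability_study(
    cohort,
    design: str,
    n_images: int | None = None,
    seed: int = 0,
    methods: Iterable[str] = METHODS,
    model: str = "two-way-random-absolute",
) -> Mapping[str, ICCResult]:
    """Intra- or inter-observer ICCs on a deterministic tibia subsample.

    ``design='intra'`` compares one rater's two sessions on a subset of
    (default) 22 tibias; ``design='inter'`` compares two raters' first
    sessions on (default) 44 tibias. ``cohort`` may be a simulated
    CohortTruth or a long-format angle table already containing the
    required raters/sessions.
    """
    frame = _angle_frame(cohort)
    raters = sorted(frame["rater"].unique())
    sessions = sorted(frame["session"].unique())
    if design == "intra":
        if len(sessions) < 2:
            raise ValueError("intra-observer design needs ≥2 sessions per rater")
        columns = [(raters[0], sessions[0]), (raters[0], sessions[1])]
        n_images = 22 if n_images is None else n_images
    elif design == "inter":
        if len(raters) < 2:
            raise ValueError("inter-observer design needs ≥2 raters")
        columns = [(raters[0], sessions[0]), (raters[1], sessions[0])]
        n_images = 44 if n_images is None else n_images
    else:
        raise ValueError(f"design must be 'intra' or 'inter', got {design!r}")

    tibias = sorted(
        set(zip(frame["subject_id"], frame["side"], strict=True))
    )
    if n_images > len(tibias):
        raise ValueError(
            f"requested {n_images} tibias but cohort has only {len(tibias)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tibias), size=n_images, replace=False)
    subset = [tibias[i] for i in sorted(idx)]

    out: dict[str, ICCResult] = {}
    for method in methods:
        matrix = ratings_matrix(frame, method, columns, tibias=subset)
        out[method] = icc(matrix, model=model)
    return out
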