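"""Study-level model: fit the full method-comparison analysis to a cohort.

:class:`TorsionStudy` is the modelling entry point: construct it from a
long-format angle table (or directly from landmark sets / a simulated
cohort), call :meth:`TorsionStudy.fit`, and read the results off the
returned :class:`TorsionStudyResults` — per-method distribution summaries,
the paired proximal (PTTA vs PMTPA) and distal (IMA vs TA) method
comparisons with correlations, composed torsion angles (TTA1/TTA2), and,
when the table carries repeated readings, intra-/inter-observer ICCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .measures import METHODS, measure_cohort, measurements_to_frame
from .stats import (
    CorrelationResult,
    ICCResult,
    PairedTestResult,
    SummaryRow,
    paired_compare,
    pearson_with_ci,
    reliability_study,
    summarize,
)

__all__ = ["TorsionStudy", "TorsionStudyResults"]

_ANGLE_COLUMNS = ["subject_id", "side", "rater", "session", "method", "value"]

#: the two method pairs every study compares
COMPARISONS = (("PTTA", "PMTPA"), ("IMA", "TA"))


class TorsionStudy:
    """Method-comparison study over a long-format angle table.

    Parameters
    ----------
    angles
        DataFrame with columns ``subject_id, side, rater, session,
        method, value`` — one row per angle reading. Angle values are
        anatomical degrees.
    """

    def __init__(self, angles: pd.DataFrame):
        missing = set(_ANGLE_COLUMNS) - set(angles.columns)
        if missing:
            raise ValueError(f"angle table missing column(s) {sorted(missing)}")
        bad = set(angles["method"].unique()) - set(METHODS)
        if bad:
            raise ValueError(f"unknown method label(s) {sorted(bad)}")
        self.angles = angles.loc[:, _ANGLE_COLUMNS].copy()

    @classmethod
    def from_landmarks(cls, landmark_sets) -> "TorsionStudy":
        """Measure labeled landmark sets and build the study from the angles."""
        records, exclusions = measure_cohort(landmark_sets)
        study = cls(measurements_to_frame(records))
        study.exclusions = exclusions
        return study

    @classmethod
    def from_cohort(cls, cohort) -> "TorsionStudy":
        """Build from a simulated :class:`~tibtorsion.simulate.CohortTruth`."""
        return cls.from_landmarks(cohort.landmarks)

    # -- fitting -----------------------------------------------------------

    def _primary_table(self) -> pd.DataFrame:
        """One reading per tibia: first rater, first session (the main read)."""
        rater = sorted(self.angles["rater"].unique())[0]
        session = sorted(self.angles["session"].unique())[0]
        sub = self.angles[
            (self.angles["rater"] == rater) & (self.angles["session"] == session)
        ]
        return sub.pivot_table(
            index=["subject_id", "side"], columns="method", values="value",
            aggfunc="first",
        ).sort_index()

    def fit(
        self,
        alpha: float = 0.05,
        icc_model: str = "two-way-random-absolute",
        intra_images: int = 22,
        inter_images: int = 44,
        subset_seed: int = 0,
    ) -> "TorsionStudyResults":
        """Run the full analysis; reliability designs run when supported."""
        wide = self._primary_table()
        present = [m for m in METHODS if m in wide.columns]

        summaries = {m: summarize(wide[m].to_numpy(), m, alpha) for m in present}

        comparisons: dict[str, PairedTestResult] = {}
        correlations: dict[str, CorrelationResult] = {}
        for m1, m2 in COMPARISONS:
            if m1 in wide.columns and m2 in wide.columns:
                pair = wide[[m1, m2]].dropna()
                key = f"{m1}_vs_{m2}"
                comparisons[key] = paired_compare(pair[m1], pair[m2], alpha)
                correlations[key] = pearson_with_ci(pair[m1], pair[m2], alpha)

        torsion = None
        torsion_summaries: dict[str, SummaryRow] = {}
        if {"PMTPA", "IMA", "TA"} <= set(wide.columns):
            torsion = wide.dropna(subset=["PMTPA", "IMA", "TA"]).copy()
            torsion["TTA1"] = torsion["IMA"] - torsion["PMTPA"]
            torsion["TTA2"] = torsion["TA"] - torsion["PMTPA"]
            for name in ("TTA1", "TTA2"):
                torsion_summaries[name] = summarize(
                    torsion[name].to_numpy(), name, alpha
                )

        iccs: dict[str, Mapping[str, ICCResult]] = {}
        n_sessions = self.angles["session"].nunique()
        n_raters = self.angles["rater"].nunique()
        n_tibias = len(wide)
        if n_sessions >= 2 and n_tibias >= max(5, intra_images):
            iccs["intra"] = reliability_study(
                self.angles, "intra", n_images=intra_images,
                seed=subset_seed, methods=present, model=icc_model,
            )
        if n_raters >= 2 and n_tibias >= max(5, inter_images):
            iccs["inter"] = reliability_study(
                self.angles, "inter", n_images=inter_images,
                seed=subset_seed, methods=present, model=icc_model,
            )

        return TorsionStudyResults(
            model=self,
            wide=wide,
            summaries=summaries,
            comparisons=comparisons,
            correlations=correlations,
            torsion=torsion,
            torsion_summaries=torsion_summaries,
            iccs=iccs,
            alpha=alpha,
        )


@dataclass
class TorsionStudyResults:
    """Fitted results of a :class:`TorsionStudy`."""

    model: TorsionStudy
    wide: pd.DataFrame = field(repr=False)
    summaries: dict[str, SummaryRow]
    comparisons: dict[str, PairedTestResult]
    correlations: dict[str, CorrelationResult]
    torsion: pd.DataFrame | None = field(repr=False)
    torsion_summaries: dict[str, SummaryRow]
    iccs: dict[str, Mapping[str, ICCResult]]
    alpha: float = 0.05

    # -- tabular views -----------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Distribution table: one column per method, classic summary rows."""
        cols = {}
        for m, s in self.summaries.items():
            cols[m] = {
                "N": s.n, "Missing": s.missing, "Mean": s.mean,
                "Median": s.median, "SD": s.sd, "Min": s.min, "Max": s.max,
                "Shapiro-Wilk p": s.normality_p, "Display": s.display,
            }
        return pd.DataFrame(cols)

    def torsion_summary_frame(self) -> pd.DataFrame:
        cols = {}
        for name, s in self.torsion_summaries.items():
            cols[name] = {"N": s.n, "Mean": s.mean, "SD": s.sd,
                          "Median": s.median, "Min": s.min, "Max": s.max}
        return pd.DataFrame(cols)

    def summary(self) -> str:
        """Plain-text report: distributions, comparisons, reliability."""
        lines = ["Torsion method-comparison study", "=" * 47, ""]
        lines.append("Angle distributions (degrees):")
        lines.append(self.summary_frame().round(3).to_string())
        if self.torsion_summaries:
            lines += ["", "Composed torsion angles (degrees):"]
            lines.append(self.torsion_summary_frame().round(3).to_string())
        if self.comparisons:
            lines += ["", "Paired method comparisons:"]
            for key, res in self.comparisons.items():
                lines.append(
                    f"  {key}: {res.test_name}, mean diff "
                    f"{res.mean_difference:+.3f}°, p = {res.p_value:.3g} "
                    f"(normality p = {res.normality_p:.3g})"
                )
        if self.correlations:
            lines += ["", "Pearson correlations (Fisher-z 95% CI):"]
            for key, res in self.correlations.items():
                lines.append(
                    f"  {key}: r = {res.r:.4f} "
                    f"[{res.ci_low:.4f}, {res.ci_high:.4f}], "
                    f"p = {res.p_value:.3g}, n = {res.n}"
                )
        for design, per_method in self.iccs.items():
            lines += ["", f"{design.capitalize()}-observer reliability (ICC):"]
            for method, res in per_method.items():
                lines.append(
                    f"  {method}: ICC = {res.estimate:.3f} "
                    f"[{res.ci_low:.3f}, {res.ci_high:.3f}] — {res.band} "
                    f"({res.n_subjects} tibias × {res.n_raters} readings)"
                )
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_agreement(self, pair: tuple[str, str] = ("IMA", "TA"), ax=None):
        """Scatter of one method against the other with the identity line."""
        import matplotlib.pyplot as plt

        m1, m2 = pair
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        data = self.wide[[m1, m2]].dropna()
        ax.scatter(data[m2], data[m1], s=12, alpha=0.6, edgecolor="none")
        lo = float(np.nanmin(data.to_numpy()))
        hi = float(np.nanmax(data.to_numpy()))
        ax.plot([lo, hi], [lo, hi], color="grey", lw=1, ls="--", label="identity")
        key = f"{m1}_vs_{m2}"
        if key in self.correlations:
            ax.set_title(f"{m1} vs {m2}: r = {self.correlations[key].r:.3f}")
        ax.set_xlabel(f"{m2} (°)")
        ax.set_ylabel(f"{m1} (°)")
        ax.legend(frameon=False)
        return ax
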