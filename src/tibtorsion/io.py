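"""File formats: landmark files, torsion-record tables, truth tables, reports.

The canonical interchange format is a flat CSV with one landmark per row::

    subject_id,side,slice,structure,point_index,x_mm,y_mm,rater,session

A JSON mirror carries the same content hierarchically (one object per
landmark set). Row order never affects results; the key
(subject_id, side, slice, structure, point_index, rater, session) must be
unique. Coordinates are written at full float precision so a write → read
round trip is exact; derived angle tables are written at 3 decimals.

No pixel-level image format is read here by design: any upstream tool that
exports labeled points in this schema can feed the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet, LandmarkValidationError
from .measures import TorsionRecord

__all__ = [
    "LANDMARK_COLUMNS",
    "read_landmarks",
    "read_records_csv",
    "write_landmarks_csv",
    "write_landmarks_json",
    "write_records_csv",
    "write_summary_csv",
    "write_truth_csv",
]

LANDMARK_COLUMNS = [
    "subject_id", "side", "slice", "structure",
    "point_index", "x_mm", "y_mm", "rater", "session",
]


def landmarks_to_frame(landmark_sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    rows = []
    for lm in landmark_sets:
        for structure, pts in lm.structures.items():
            for i, (x, y) in enumerate(pts):
                rows.append(
                    {
                        "subject_id": lm.subject_id,
                        "side": lm.side,
                        "slice": lm.slice_name,
                        "structure": structure,
                        "point_index": i,
                        "x_mm": float(x),
                        "y_mm": float(y),
                        "rater": lm.rater,
                        "session": int(lm.session),
                    }
                )
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def write_landmarks_csv(landmark_sets: Iterable[LandmarkSet], path) -> None:
    frame = landmarks_to_frame(landmark_sets)
    frame.to_csv(path, index=False, float_format="%.17g")


def write_landmarks_json(landmark_sets: Iterable[LandmarkSet], path) -> None:
    payload = [
        {
            "subject_id": lm.subject_id,
            "side": lm.side,
            "slice": lm.slice_name,
            "rater": lm.rater,
            "session": int(lm.session),
            "structures": {k: v.tolist() for k, v in lm.structures.items()},
        }
        for lm in landmark_sets
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _sets_from_frame(frame: pd.DataFrame, source: str) -> list[LandmarkSet]:
    missing = set(LANDMARK_COLUMNS) - set(frame.columns)
    if missing:
        raise LandmarkValidationError(
            f"{source}: missing column(s) {sorted(missing)}"
        )
    # surface non-numeric coordinates with the offending row number
    for col in ("x_mm", "y_mm", "point_index", "session"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad) or frame[col].isna().any():
            row = int((frame.index[frame[col].isna()].tolist() + bad.tolist())[0])
            raise LandmarkValidationError(
                f"{source}, row {row + 2}: non-numeric {col} value "
                f"{frame.loc[row, col]!r}"
            )
        frame[col] = coerced
    dup = frame.duplicated(
        subset=["subject_id", "side", "slice", "structure",
                "point_index", "rater", "session"]
    )
    if dup.any():
        row = int(frame.index[dup][0])
        raise LandmarkValidationError(
            f"{source}, row {row + 2}: duplicate landmark key "
            f"{tuple(frame.loc[row, ['subject_id', 'side', 'slice', 'structure', 'point_index']])}"
        )

    sets: list[LandmarkSet] = []
    group_cols = ["subject_id", "side", "rater", "session", "slice"]
    for (subject, side, rater, session, slice_name), grp in sorted(
        frame.groupby(group_cols, sort=True), key=lambda kv: tuple(map(str, kv[0]))
    ):
        structures = {}
        for structure, pts in grp.groupby("structure"):
            ordered = pts.sort_values("point_index")
            structures[structure] = ordered[["x_mm", "y_mm"]].to_numpy(dtype=float)
        try:
            sets.append(
                LandmarkSet(
                    subject_id=str(subject),
                    side=str(side),
                    slice_name=str(slice_name),
                    structures=structures,
                    rater=str(rater),
                    session=int(session),
                )
            )
        except LandmarkValidationError as exc:
            row = int(grp.index[0])
            raise LandmarkValidationError(
                f"{source}, rows near {row + 2}: {exc}"
            ) from exc
    return sets


def read_landmarks(path, format: str | None = None) -> list[LandmarkSet]:
    """Read and validate a landmark file (CSV or JSON, by extension).

    Returns landmark sets grouped by (subject, side, rater, session) and
    slice, in deterministic sorted order; row order in the file is
    irrelevant to downstream results.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(
            path, dtype={"subject_id": str, "rater": str},
            float_precision="round_trip",
        )
        return _sets_from_frame(frame, path.name)
    if fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        sets = []
        for i, entry in enumerate(payload):
            try:
                sets.append(
                    LandmarkSet(
                        subject_id=str(entry["subject_id"]),
                        side=str(entry["side"]),
                        slice_name=str(entry["slice"]),
                        structures={
                            k: np.asarray(v, dtype=float)
                            for k, v in entry["structures"].items()
                        },
                        rater=str(entry.get("rater", "r1")),
                        session=int(entry.get("session", 1)),
                    )
                )
            except (KeyError, ValueError, LandmarkValidationError) as exc:
                raise LandmarkValidationError(
                    f"{path.name}, entry {i}: {exc}"
                ) from exc
        sets.sort(key=lambda lm: (lm.key, lm.slice_name))
        return sets
    raise ValueError(f"unknown landmark format {fmt!r}; use 'csv' or 'json'")


def write_records_csv(records: Iterable[TorsionRecord], path) -> None:
    """Torsion-record table, angles at 3 decimals."""
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id, "side": r.side,
                "ptta": r.ptta, "pmtpa": r.pmtpa, "ima": r.ima, "ta": r.ta,
                "tta1": r.tta1, "tta2": r.tta2,
                "rater": r.rater, "session": r.session,
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False, float_format="%.3f")


def read_records_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str, "rater": str})
    required = {"subject_id", "side", "ptta", "pmtpa", "ima", "ta"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {sorted(missing)}")
    return frame


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format="%.6f")


def write_summary_csv(summary_frame: pd.DataFrame, path) -> None:
    """Distribution-table CSV: methods as columns, summary statistics as rows."""
    summary_frame.to_csv(path, float_format="%.3f")
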