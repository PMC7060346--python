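"""Readers and writers for the pipeline's plain-text data formats.

All CSVs are UTF-8, comma-separated, header row, '.' decimal separator.
Readers validate the documented schema and raise :class:`SchemaError`
naming the file, row (1-based data row) and column of the first violation;
writers round-trip losslessly through the readers.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .rr import RRSeries

__all__ = [
    "read_subjects", "read_task_trials", "read_tracking_trials",
    "read_questionnaires", "read_rr", "write_rr", "write_dataset",
    "read_dataset",
]

_TASK_TYPES = {"go", "nogo", "choose"}
_PHASES = {"systole", "diastole"}

QUESTIONNAIRE_COLUMNS = [
    "subject_id", "bis_attention", "bis_motor", "bis_planning", "bis_total",
    "caars_adhd", "upps_neg_urgency", "upps_premeditation",
    "upps_perseverance", "upps_sensation", "upps_pos_urgency", "bpq_mean"]


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", path=path)


def _bad_row(mask: pd.Series):
    """First offending 1-based data row, or None."""
    idx = np.flatnonzero(mask.to_numpy())
    return int(idx[0]) + 1 if idx.size else None


def read_subjects(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id"], path)
    if df["subject_id"].isna().any() or df["subject_id"].duplicated().any():
        raise SchemaError("subject_id must be unique and non-blank",
                          path=path, column="subject_id")
    return df


def read_task_trials(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "trial_index", "trial_type",
                          "intended_phase", "cue_onset_ms", "pressed",
                          "rt_ms"], path)
    row = _bad_row(~df["trial_type"].isin(_TASK_TYPES))
    if row:
        raise SchemaError("trial_type must be go|nogo|choose",
                          path=path, row=row, column="trial_type")
    row = _bad_row(~df["intended_phase"].isin(_PHASES))
    if row:
        raise SchemaError("intended_phase must be systole|diastole",
                          path=path, row=row, column="intended_phase")
    row = _bad_row(~df["pressed"].isin([0, 1]))
    if row:
        raise SchemaError("pressed must be 0 or 1",
                          path=path, row=row, column="pressed")
    row = _bad_row((df["pressed"] == 1) & df["rt_ms"].isna())
    if row:
        raise SchemaError("blank rt_ms with pressed=1",
                          path=path, row=row, column="rt_ms")
    row = _bad_row((df["pressed"] == 0) & df["rt_ms"].notna())
    if row:
        raise SchemaError("rt_ms present with pressed=0",
                          path=path, row=row, column="rt_ms")
    row = _bad_row(df["rt_ms"].notna() & ~(df["rt_ms"] > 0))
    if row:
        raise SchemaError("rt_ms must be positive",
                          path=path, row=row, column="rt_ms")
    return df


def read_tracking_trials(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id", "trial_index", "duration_s",
                          "nbeats_real", "nbeats_reported", "confidence"], path)
    row = _bad_row(~(df["nbeats_real"] >= 1))
    if row:
        raise SchemaError("nbeats_real must be >= 1",
                          path=path, row=row, column="nbeats_real")
    row = _bad_row(~(df["nbeats_reported"] >= 0))
    if row:
        raise SchemaError("nbeats_reported must be >= 0",
                          path=path, row=row, column="nbeats_reported")
    row = _bad_row(~df["confidence"].between(0, 10))
    if row:
        raise SchemaError("confidence must lie in [0, 10]",
                          path=path, row=row, column="confidence")
    return df


def read_questionnaires(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, ["subject_id"], path)
    if "bpq_mean" in df.columns:
        row = _bad_row(df["bpq_mean"].notna() & ~df["bpq_mean"].between(1, 5))
        if row:
            raise SchemaError("bpq_mean must lie in [1, 5]",
                              path=path, row=row, column="bpq_mean")
    return df


def read_rr(path) -> RRSeries:
    """One ascending R-peak time (ms) per line."""
    path = Path(path)
    try:
        times = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as e:
        raise SchemaError(f"non-numeric R-peak time ({e})", path=path) from e
    d = np.diff(times)
    if d.size and not np.all(d > 0):
        raise SchemaError("R-peak times must be strictly increasing",
                          path=path, row=int(np.flatnonzero(d <= 0)[0]) + 2)
    return RRSeries(times)


def write_rr(rr: RRSeries, path):
    path = Path(path)
    np.savetxt(path, rr.r_times, fmt="%.1f")
    return path


def write_dataset(cohort: dict, outdir) -> list:
    """Write a generated cohort bundle; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ("subjects", "task_trials", "tracking_trials", "questionnaires"):
        p = outdir / f"{name}.csv"
        cohort[name].to_csv(p, index=False)
        paths.append(p)
    for sid, rr in cohort["rr"].items():
        paths.append(write_rr(rr, outdir / f"rr_{sid}.txt"))
    return paths


def read_dataset(indir) -> dict:
    """Read a dataset directory back into the in-memory bundle layout."""
    indir = Path(indir)
    subjects = read_subjects(indir / "subjects.csv")
    rr = {sid: read_rr(indir / f"rr_{sid}.txt")
          for sid in subjects["subject_id"]
          if (indir / f"rr_{sid}.txt").exists()}
    return {
        "subjects": subjects,
        "task_trials": read_task_trials(indir / "task_trials.csv"),
        "tracking_trials": read_tracking_trials(indir / "tracking_trials.csv"),
        "questionnaires": read_questionnaires(indir / "questionnaires.csv"),
        "rr": rr,
    }
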