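"""Readers/writers for the gaze TSV dialect and the covariate CSV.

The dialect is one sample per row, tab-separated, with columns
``timestamp_ms, left_x_px, left_y_px, right_x_px, right_y_px, left_valid,
right_valid, trial_index, interval_label`` plus two self-describing target
columns ``target_side`` and ``target_ecc_deg`` so a file carries its own
trial schedule.  Positions are written with 4 decimals, validity as 0/1,
and missing positions as empty fields; reading then rewriting a canonical
file is byte-identical.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import ParadigmSpec, ScreenGeometry, TrialTemplate
from .preprocess import GazeRecording

__all__ = ["GAZE_COLUMNS", "read_gaze_tsv", "write_gaze_tsv",
           "read_covariates_csv", "write_covariates_csv"]

GAZE_COLUMNS = (
    "timestamp_ms", "left_x_px", "left_y_px", "right_x_px", "right_y_px",
    "left_valid", "right_valid", "trial_index", "interval_label",
)
TARGET_COLUMNS = ("target_side", "target_ecc_deg")


def write_gaze_tsv(rec: GazeRecording, path) -> None:
    """Write a recording in the canonical TSV dialect."""
    def fmt_pos(a):
        return ["" if not np.isfinite(v) else f"{v:.4f}" for v in a]

    t_ms = rec.t_us / 1000.0
    ts = [f"{v:.3f}".rstrip("0").rstrip(".") for v in t_ms]
    side = np.full(rec.n_samples, "", dtype=object)
    ecc = np.full(rec.n_samples, "", dtype=object)
    for k, tpl in enumerate(rec.schedule):
        sel = rec.trial_index == k
        side[sel] = tpl.side
        ecc[sel] = f"{tpl.eccentricity_deg:g}"
    df = pd.DataFrame({
        "timestamp_ms": ts,
        "left_x_px": fmt_pos(rec.left_x_px),
        "left_y_px": fmt_pos(rec.left_y_px),
        "right_x_px": fmt_pos(rec.right_x_px),
        "right_y_px": fmt_pos(rec.right_y_px),
        "left_valid": rec.left_valid.astype(int),
        "right_valid": rec.right_valid.astype(int),
        "trial_index": rec.trial_index,
        "interval_label": rec.interval_label,
        "target_side": side,
        "target_ecc_deg": ecc,
    })
    df.to_csv(path, sep="\t", index=False)


def _schedule_from_frame(df: pd.DataFrame, spec: ParadigmSpec) -> list[TrialTemplate]:
    bounds = tuple(float(b) for b in spec.boundaries_ms)
    templates = []
    for k in sorted(df.loc[df["trial_index"] >= 0, "trial_index"].unique()):
        sub = df[df["trial_index"] == k]
        side = str(sub["target_side"].iloc[0])
        ecc = float(sub["target_ecc_deg"].iloc[0])
        templates.append(TrialTemplate(
            index=int(k), side=side, eccentricity_deg=ecc,
            start_ms=float(sub["timestamp_ms"].iloc[0]), boundaries_ms=bounds))
    return templates


def read_gaze_tsv(path, geometry: ScreenGeometry = ScreenGeometry(),
                  schedule: list[TrialTemplate] | None = None,
                  paradigm: ParadigmSpec = ParadigmSpec()) -> GazeRecording:
    """Parse a gaze TSV into a GazeRecording.

    Mandatory columns are those of :data:`GAZE_COLUMNS`; the target columns
    are used to rebuild the trial schedule unless one is supplied.  Rows
    with unparseable fields are dropped, counted, and reported via a
    warning; missing mandatory columns and non-monotone timestamps are hard
    errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"interval_label": str, "target_side": str})
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path.name}")
    n_raw = len(df)
    num_cols = ["timestamp_ms", "left_valid", "right_valid", "trial_index"]
    for col in num_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=num_cols)
    if len(df) < n_raw:
        warnings.warn(f"{path.name}: dropped {n_raw - len(df)} malformed rows")
    t_ms = df["timestamp_ms"].to_numpy(float)
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError(f"{path.name}: timestamps are not strictly increasing")
    if schedule is None:
        if not all(c in df.columns for c in TARGET_COLUMNS):
            raise ValueError("no schedule supplied and no target columns in file")
        schedule = _schedule_from_frame(df, paradigm)
    pos = {c: pd.to_numeric(df[c], errors="coerce").to_numpy(float)
           for c in ("left_x_px", "left_y_px", "right_x_px", "right_y_px")}
    return GazeRecording(
        t_us=np.round(t_ms * 1000).astype(np.int64),
        left_x_px=pos["left_x_px"], left_y_px=pos["left_y_px"],
        right_x_px=pos["right_x_px"], right_y_px=pos["right_y_px"],
        left_valid=df["left_valid"].to_numpy() > 0,
        right_valid=df["right_valid"].to_numpy() > 0,
        geometry=geometry, schedule=schedule,
        trial_index=df["trial_index"].to_numpy(int),
        interval_label=df["interval_label"].to_numpy(object),
    )


def write_covariates_csv(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("covariate table must have a subject_id column")
    for col, hi in (("MOTS-1", 30), ("HDTSA-1", 21), ("HDTSD-1", 21)):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if ((vals < 0) | (vals > hi)).any():
                raise ValueError(f"{col} outside its standard range [0, {hi}]")
    return df
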