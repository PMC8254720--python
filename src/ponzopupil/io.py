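"""On-disk formats: sample TSV, trial/participant CSVs, reports.

Formats
-------
samples.tsv
    One row per eye-tracker sample: participant_id, block, trial, t_ms,
    pupil, gaze_x_px, gaze_y_px.  Missing samples leave fields empty.
trials.csv
    participant_id, block, trial, size_level, location, report_mm.
participants.csv
    participant_id, aq, gender.
ground_truth.csv
    Generator sidecar: perceived heights, context gain and the exact
    corrupted sample indices per trial (semicolon-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import TrialCondition
from .preprocess import RawTrace, TrialRecord
from .simulate import SimulatedSession

SAMPLE_COLUMNS = ["participant_id", "block", "trial", "t_ms", "pupil",
                  "gaze_x_px", "gaze_y_px"]
TRIAL_COLUMNS = ["participant_id", "block", "trial", "size_level", "location",
                 "report_mm"]


def write_dataset(sessions: Sequence[SimulatedSession], outdir) -> dict:
    """Write a simulated dataset in the reader formats; returns a digest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_frames, trial_rows, part_rows, truth_frames = [], [], [], []
    n_corrupted = 0
    for session in sessions:
        for rec in session.trials:
            cond = rec.condition
            sample_frames.append(pd.DataFrame({
                "participant_id": rec.participant_id,
                "block": cond.block,
                "trial": cond.trial_index_in_block,
                "t_ms": rec.trace.t_ms,
                "pupil": rec.trace.pupil_mm,
                "gaze_x_px": rec.trace.gaze_x_px,
                "gaze_y_px": rec.trace.gaze_y_px,
            }))
            trial_rows.append({
                "participant_id": rec.participant_id,
                "block": cond.block,
                "trial": cond.trial_index_in_block,
                "size_level": cond.size_level,
                "location": cond.location,
                "report_mm": rec.report_mm,
            })
        part_rows.append({"participant_id": session.participant_id,
                          "aq": session.aq_score.score,
                          "gender": session.gender})
        truth_frames.append(session.ground_truth)
        n_corrupted += int(session.ground_truth["n_corrupted"].sum())

    samples = pd.concat(sample_frames, ignore_index=True)
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False,
                   float_format="%.6g")
    pd.DataFrame(trial_rows).to_csv(outdir / "trials.csv", index=False)
    pd.DataFrame(part_rows).to_csv(outdir / "participants.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        outdir / "ground_truth.csv", index=False
    )
    return {
        "n_participants": len(sessions),
        "n_trials": len(trial_rows),
        "n_samples": int(len(samples)),
        "n_corrupted_samples": n_corrupted,
    }


def read_dataset(datadir) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Read samples.tsv + trials.csv (+ participants.csv) back into records.

    An optional per-file pupil scale factor is not applied here; pupil
    values are assumed to be mm post-calibration.
    """
    datadir = Path(datadir)
    samples = pd.read_csv(datadir / "samples.tsv", sep="\t")
    trials = pd.read_csv(datadir / "trials.csv")
    participants_path = datadir / "participants.csv"
    participants = (pd.read_csv(participants_path)
                    if participants_path.exists() else pd.DataFrame())
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"samples.tsv missing columns: {missing}")

    records: list[TrialRecord] = []
    grouped = samples.groupby(["participant_id", "block", "trial"], sort=True)
    meta = trials.set_index(["participant_id", "block", "trial"])
    for key, grp in grouped:
        try:
            row = meta.loc[key]
        except KeyError as exc:
            raise ValueError(f"trial metadata missing for {key}") from exc
        grp = grp.sort_values("t_ms")
        trace = RawTrace(
            t_ms=grp["t_ms"].to_numpy(dtype=float),
            pupil_mm=grp["pupil"].to_numpy(dtype=float),
            gaze_x_px=grp["gaze_x_px"].to_numpy(dtype=float),
            gaze_y_px=grp["gaze_y_px"].to_numpy(dtype=float),
        )
        cond = TrialCondition(
            size_level=int(row["size_level"]), location=str(row["location"]),
            repetition=1, block=int(key[1]), trial_index_in_block=int(key[2]),
        )
        records.append(TrialRecord(participant_id=str(key[0]), condition=cond,
                                   report_mm=float(row["report_mm"]), trace=trace))
    return records, participants


def validate_inputs(datadir, rate_tol: float = 0.05) -> list[dict]:
    """Check a dataset directory for format problems; never mutates data.

    Findings cover: non-monotone timestamps, sample spacing away from
    the nominal 500 Hz, implausible pupil values, unbalanced designs and
    out-of-range AQ scores.  Returns a (possibly empty) list of finding
    dicts.
    """
    datadir = Path(datadir)
    findings: list[dict] = []

    samples = pd.read_csv(datadir / "samples.tsv", sep="\t")
    for key, grp in samples.groupby(["participant_id", "block", "trial"]):
        t = grp["t_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(grp.index[np.argmax(dt <= 0) + 1]) + 2  # header + 0-base
            findings.append({"kind": "non_monotone_timestamps", "trial": key,
                             "line": line})
        elif len(dt) and abs(np.median(dt) - 2.0) > rate_tol * 2.0:
            findings.append({"kind": "sampling_rate_off_nominal", "trial": key,
                             "median_dt_ms": float(np.median(dt))})
        pupil = grp["pupil"].to_numpy(dtype=float)
        finite = pupil[np.isfinite(pupil)]
        if finite.size and (finite.min() < 0 or finite.max() > 12):
            findings.append({"kind": "implausible_pupil", "trial": key,
                             "range": [float(finite.min()), float(finite.max())]})

    trials = pd.read_csv(datadir / "trials.csv")
    for pid, grp in trials.groupby("participant_id"):
        counts = grp.groupby(["size_level", "location"]).size()
        if counts.nunique() > 1:
            findings.append({"kind": "unbalanced_design", "participant": pid,
                             "cell_counts": counts.to_dict()})

    ppath = datadir / "participants.csv"
    if ppath.exists():
        participants = pd.read_csv(ppath)
        bad = participants[(participants["aq"] < 0) | (participants["aq"] > 50)]
        for _, row in bad.iterrows():
            findings.append({"kind": "aq_out_of_range",
                             "participant": row["participant_id"],
                             "aq": int(row["aq"]),
                             "bound": "AQ scores lie in 0-50"})
    return findings


def write_json(obj, path) -> None:
    """Serialize a report bundle deterministically (sorted keys)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=default,
                   allow_nan=True) + "\n"
    )
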