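"""Trial-table and record I/O.

Trial tables are plain CSV (UTF-8, '.' decimal separator) with one row per
trial, plus a sidecar JSON mapping "mouse|session|index" keys to per-trial
puff event lists, so the full stimulus timing survives a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task_sim import LearningTimeRecord, PuffEvent, TrialRecord

TRIAL_COLUMNS = [
    "mouse_id", "session_id", "trial_index", "level", "cue_duration", "delay",
    "n_left", "n_right", "delta_cues", "correct_side", "choice", "rewarded",
    "latent_state",
]


def _trial_key(t: TrialRecord) -> str:
    return f"{t.mouse_id}|{t.session_id}|{t.trial_index}"


def write_trial_table(trials: list[TrialRecord], csv_path, sidecar_path=None) -> None:
    """Write trials to CSV plus an optional puff-time sidecar JSON."""
    rows = []
    for t in trials:
        rows.append({
            "mouse_id": t.mouse_id, "session_id": t.session_id,
            "trial_index": t.trial_index, "level": t.level,
            "cue_duration": t.cue_duration, "delay": t.delay,
            "n_left": t.n_left, "n_right": t.n_right,
            "delta_cues": t.delta_cues, "correct_side": t.correct_side,
            "choice": t.choice, "rewarded": t.rewarded,
            "latent_state": "" if t.latent_state is None else t.latent_state,
        })
    # %.17g guarantees exact float round-trips
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(csv_path, index=False,
                                                     float_format="%.17g")
    if sidecar_path is not None:
        sidecar = {
            _trial_key(t): [[p.time, p.side, p.kind] for p in t.puffs]
            for t in trials
        }
        Path(sidecar_path).write_text(json.dumps(sidecar))


def read_trial_table(csv_path, sidecar_path=None) -> list[TrialRecord]:
    """Read a trial table (and optional sidecar); inverse of
    :func:`write_trial_table` on every field.

    Handles BOM and CRLF line endings transparently.  Missing or malformed
    columns raise a parse error naming the offending columns.
    """
    df = pd.read_csv(csv_path, encoding="utf-8-sig", float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    sidecar = {}
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text(encoding="utf-8-sig"))

    trials = []
    for i, row in df.iterrows():
        try:
            ls = row["latent_state"]
            latent = None if pd.isna(ls) or ls == "" else int(ls)
            t = TrialRecord(
                mouse_id=str(row["mouse_id"]), session_id=str(row["session_id"]),
                trial_index=int(row["trial_index"]), level=int(row["level"]),
                cue_duration=float(row["cue_duration"]), delay=float(row["delay"]),
                n_left=int(row["n_left"]), n_right=int(row["n_right"]),
                delta_cues=int(row["delta_cues"]),
                correct_side=str(row["correct_side"]), choice=str(row["choice"]),
                rewarded=bool(row["rewarded"]), latent_state=latent,
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"malformed trial-table row at line {i + 2}: {e}") from e
        key = _trial_key(t)
        if key in sidecar:
            t.puffs = [PuffEvent(float(tt), s, k) for tt, s, k in sidecar[key]]
        trials.append(t)
    return trials


def write_learning_times(records: list[LearningTimeRecord], path) -> None:
    pd.DataFrame([{
        "mouse_id": r.mouse_id, "group": r.group,
        "trials_observed": r.trials_observed, "completed": r.completed,
    } for r in records]).to_csv(path, index=False)


def read_learning_times(path) -> list[LearningTimeRecord]:
    df = pd.read_csv(path, encoding="utf-8-sig", float_precision="round_trip")
    missing = [c for c in ("mouse_id", "group", "trials_observed", "completed")
               if c not in df.columns]
    if missing:
        raise ValueError(f"learning-time table missing columns: {missing}")
    return [LearningTimeRecord(str(r.mouse_id), str(r.group),
                               int(r.trials_observed), bool(r.completed))
            for r in df.itertuples()]


def append_decode_columns(csv_path, gamma: np.ndarray, out_path=None) -> None:
    """Append per-trial posterior columns gamma_1..gamma_K and map_state to
    an existing trial-table CSV."""
    df = pd.read_csv(csv_path, encoding="utf-8-sig", float_precision="round_trip")
    if len(df) != gamma.shape[0]:
        raise ValueError("decode length does not match trial table")
    for k in range(gamma.shape[1]):
        df[f"gamma_{k + 1}"] = gamma[:, k]
    df["map_state"] = np.argmax(gamma, axis=1)
    df.to_csv(out_path or csv_path, index=False)
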