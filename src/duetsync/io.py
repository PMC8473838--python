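"""Readers and writers for the pipeline's on-disk formats.

Event tables are UTF-8 TSV with a fixed header; EEG recordings are a flat
little-endian float32 binary (channels x samples, C order) next to a JSON
sidecar carrying the sampling rate, channel names, event anchors and
repetition windows.  Both round-trip losslessly (float32 for EEG samples).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import EEGRecording, PerformanceTrial

__all__ = ["write_events", "read_events", "write_eeg", "read_eeg"]

EVENT_TSV_COLUMNS = [
    "pair_id", "performer", "role", "condition", "trial_index",
    "repetition_index", "event_index", "nominal_event_index",
    "nominal_pitch", "played_pitch", "onset_ms", "beat_value",
    "is_on_beat", "matched_event_index", "end_ms", "injected_error",
]


def write_events(trials: list[PerformanceTrial], path: str | Path) -> None:
    """Write trials to one TSV event table (one row per played tone)."""
    rows = []
    for tr in trials:
        for _, ev in tr.events.iterrows():
            rows.append({
                "pair_id": tr.pair_id, "performer": tr.performer_id,
                "role": tr.role, "condition": tr.condition,
                "trial_index": tr.trial_index, "repetition_index": tr.repetition_index,
                "event_index": int(ev["event_index"]),
                "nominal_event_index": int(ev["nominal_event_index"]),
                "nominal_pitch": int(ev["nominal_pitch"]),
                "played_pitch": int(ev["played_pitch"]),
                "onset_ms": float(ev["onset_ms"]),
                "beat_value": float(ev["beat_value"]),
                "is_on_beat": bool(ev["is_on_beat"]),
                "matched_event_index": int(ev["matched_event_index"]),
                "end_ms": float(tr.end_ms) if tr.end_ms is not None else np.nan,
                "injected_error": tr.injected_error or "",
            })
    frame = pd.DataFrame(rows, columns=EVENT_TSV_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path) -> list[PerformanceTrial]:
    """Read a TSV event table back into per-repetition trials.

    Validates the schema and that onsets are strictly increasing within
    each performer x condition x repetition; violations raise with the
    offending row number.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frame["injected_error"] = frame["injected_error"].fillna("")
    trials = []
    keys = ["pair_id", "performer", "role", "condition", "trial_index", "repetition_index"]
    for key, grp in frame.groupby(keys, sort=True):
        grp = grp.sort_values("event_index")
        onsets = grp["onset_ms"].to_numpy()
        bad = np.nonzero(np.diff(onsets) <= 0)[0]
        if len(bad):
            row = int(grp.index[bad[0] + 1]) + 2  # +2: header + 1-based
            raise ValueError(f"{path}: non-monotone onset_ms at row {row}")
        pair_id, performer, role, condition, trial_index, repetition_index = key
        end = grp["end_ms"].iloc[0]
        err = grp["injected_error"].iloc[0]
        events = grp[[
            "event_index", "nominal_event_index", "nominal_pitch", "played_pitch",
            "onset_ms", "beat_value", "is_on_beat", "matched_event_index",
        ]].reset_index(drop=True)
        trials.append(PerformanceTrial(
            pair_id=int(pair_id), performer_id=str(performer), role=str(role),
            condition=str(condition), trial_index=int(trial_index),
            repetition_index=int(repetition_index), events=events,
            end_ms=None if pd.isna(end) else float(end),
            injected_error=err or None,
        ))
    trials.sort(key=lambda t: (t.pair_id, t.performer_id, t.condition, t.repetition_index))
    return trials


def write_eeg(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as ``<path>.bin`` (float32) + ``<path>.json``."""
    path = Path(path)
    data = np.ascontiguousarray(recording.data, dtype="<f4")
    data.tofile(path.with_suffix(".bin"))
    sidecar = {
        "fs": recording.fs,
        "ch_names": list(recording.ch_names),
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "<f4",
        "pair_id": recording.pair_id,
        "performer_id": recording.performer_id,
        "condition": recording.condition,
        "anchors": recording.anchors.to_dict(orient="list"),
        "rep_windows": recording.rep_windows.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_eeg(path: str | Path, *, expected_fs: float | None = None) -> EEGRecording:
    """Read a flat-binary + JSON recording written by :func:`write_eeg`."""
    path = Path(path)
    if path.suffix not in ("", ".bin", ".json"):
        raise ValueError(f"unsupported EEG format {path.suffix!r}; expected .bin/.json pair")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if expected_fs is not None and meta["fs"] != expected_fs:
        raise ValueError(f"sampling rate mismatch: file {meta['fs']} Hz, expected {expected_fs}")
    if "anchors" not in meta or not meta["anchors"]:
        raise ValueError(f"{sidecar_path}: missing event anchors")
    data = np.fromfile(path.with_suffix(".bin"), dtype=meta.get("dtype", "<f4"))
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return EEGRecording(
        data=data, fs=float(meta["fs"]), ch_names=list(meta["ch_names"]),
        anchors=pd.DataFrame(meta["anchors"]),
        rep_windows=pd.DataFrame(meta["rep_windows"]),
        pair_id=int(meta.get("pair_id", 0)),
        performer_id=str(meta.get("performer_id", "")),
        condition=str(meta.get("condition", "")),
    )
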