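"""In-memory containers shared across pipeline stages.

Conventions used everywhere: onset times are float milliseconds on the
condition timeline; EEG sample indices are 0-based integers; epochs are
half-open sample intervals ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PerformanceTrial", "EEGRecording"]

ROLES = ("Leader", "Follower")
CONDITIONS = ("First-Leader", "Second-Leader", "Solo")

#: columns of the per-event table carried by a PerformanceTrial
EVENT_COLUMNS = [
    "event_index",        # running index within the repetition (played order)
    "nominal_event_index",  # index into the melody template, -1 for inserted tones
    "nominal_pitch",      # template pitch (-1 for inserted tones)
    "played_pitch",
    "onset_ms",
    "beat_value",
    "is_on_beat",
    "matched_event_index",  # filled by the error classifier; -1 = unmatched
]


@dataclass
class PerformanceTrial:
    """One performer's onset/pitch stream for a single melody repetition."""

    pair_id: int
    performer_id: str
    role: str                 # Leader | Follower
    condition: str            # First-Leader | Second-Leader | Solo
    trial_index: int          # block of continuous repetitions
    repetition_index: int     # global repetition index within the condition
    events: pd.DataFrame      # EVENT_COLUMNS
    end_ms: float | None = None   # nominal end of the repetition (ms)
    injected_error: str | None = None  # ground-truth label from the simulator
    classification: str | None = None  # filled by behavior.classify_pitch_errors

    def __post_init__(self) -> None:
        onsets = np.asarray(self.events["onset_ms"], dtype=float)
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValueError(
                f"onsets must be strictly increasing (pair {self.pair_id}, "
                f"{self.performer_id}, rep {self.repetition_index})"
            )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.asarray(self.events["onset_ms"], dtype=float)

    @property
    def played_pitches(self) -> np.ndarray:
        return np.asarray(self.events["played_pitch"], dtype=int)

    def with_events(self, events: pd.DataFrame, **kw) -> "PerformanceTrial":
        return replace(self, events=events.reset_index(drop=True), **kw)


@dataclass
class EEGRecording:
    """Multichannel EEG time-locked to the event stream of one performer.

    ``anchors`` holds one row per tone onset with the sample index it maps
    to, keyed by (trial_index, repetition_index, event_index); repetition
    boundary samples are carried in ``rep_windows``.
    """

    data: np.ndarray          # (n_channels, n_samples) float
    fs: float                 # Hz
    ch_names: list[str]
    anchors: pd.DataFrame     # trial_index, repetition_index, event_index, sample
    rep_windows: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rep_windows columns: trial_index, repetition_index, start_sample, stop_sample
    pair_id: int = 0
    performer_id: str = ""
    condition: str = ""
    source_envelope: np.ndarray | None = None  # simulator ground truth, if any

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be (channels, samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count does not match channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        """Case-insensitive channel lookup (10-20 names vary in casing)."""
        lowered = [c.lower() for c in self.ch_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
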