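import numpy as np
import pandas as pd
import pytest

from duetsync.data import PerformanceTrial
from duetsync.melody import make_melody_spec


@pytest.fixture(scope="session")
def melody():
    return make_melody_spec()


def trial_from_onsets(
    onsets_ms,
    melody,
    *,
    pitches=None,
    nominal_indices=None,
    pair_id=0,
    performer_id="X",
    role="Leader",
    condition="First-Leader",
    repetition_index=0,
    trial_index=0,
    end_ms=None,
    matched=None,
):
    """Build a PerformanceTrial directly from onset times (test helper)."""
    n = len(onsets_ms)
    if nominal_indices is None:
        nominal_indices = list(range(n))
    events = pd.DataFrame({
        "event_index": np.arange(n),
        "nominal_event_index": nominal_indices,
        "nominal_pitch": [
            melody.events[i].pitch if 0 <= i < melody.n_events else -1
            for i in nominal_indices
        ],
        "played_pitch": pitches if pitches is not None else [
            melody.events[i].pitch if 0 <= i < melody.n_events else -1
            for i in nominal_indices
        ],
        "onset_ms": np.asarray(onsets_ms, float),
        "beat_value": [
            float(melody.events[i].beat_value) if 0 <= i < melody.n_events else np.nan
            for i in nominal_indices
        ],
        "is_on_beat": [
            melody.events[i].is_on_beat if 0 <= i < melody.n_events else False
            for i in nominal_indices
        ],
        "matched_event_index": matched if matched is not None else nominal_indices,
    })
    return PerformanceTrial(
        pair_id=pair_id, performer_id=performer_id, role=role, condition=condition,
        trial_index=trial_index, repetition_index=repetition_index,
        events=events, end_ms=end_ms,
    )


@pytest.fixture
def isochronous_trial(melody):
    """A perfectly regular performance at 500 ms per beat."""
    onsets = [float(p) * 500.0 for p in melody.beat_positions()]
    return trial_from_onsets(onsets, melody, end_ms=32 * 500.0)
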