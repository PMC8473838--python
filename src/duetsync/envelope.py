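"""Amplitude envelopes at the duet rate and inter-brain envelope correlations.

Each performer's EEG is reduced to one time course (the selected SSD
filter), band-passed in a narrow band around the pair's duet performance
rate (+-0.183 Hz, zero-phase 2nd-order Butterworth), epoched per melody
repetition with 2.5 s pads, antialias-downsampled to 100 Hz, and its
amplitude envelope taken as the magnitude of the Hilbert analytic signal
(pads trimmed to discard Hilbert edge artifacts).

Because performances of the same melody differ in timing, envelopes are
resampled onto the melodic event grid: the shortest eighth-note-equivalent
inter-onset interval (in samples) across repetitions sets the grid density
``m``; eighth notes span ``m`` samples, quarters ``2m``, halves ``4m`` (64
eighth-note units, so ``64 m`` samples per full repetition).  Shape-
preserving piecewise-cubic (PCHIP) interpolation warps each inter-onset
segment onto the grid, after which envelopes from different performances
(and different performers) are pointwise comparable.

Inter-brain amplitude envelope correlations (AECs) are Pearson
correlations per repetition, Fisher-z averaged within condition; the chance
level comes from surrogate pairs (each leader re-paired with every
non-partner follower), and observed-vs-surrogate is summarized with an
exact one-sided binomial test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal, stats

from .data import EEGRecording
from .melody import COUNT_IN_EVENTS, MelodySpec
from .ssd import apply_spatial_filter

__all__ = [
    "EnvelopeSeries",
    "RawEnvelope",
    "extract_envelope",
    "event_resample",
    "min_grid_density",
    "aec",
    "condition_aec",
    "surrogate_aecs",
    "binomial_comparison",
    "fisher_z",
    "fisher_z_mean",
]

logger = logging.getLogger(__name__)

NARROWBAND_HALFWIDTH_HZ = 0.183
ENVELOPE_FS = 100.0
PAD_S = 2.5
Z_CLIP = math.atanh(0.999999)


@dataclass
class RawEnvelope:
    """Amplitude envelope of one melody repetition at the envelope rate.

    ``onset_idx`` maps each played tone onto an envelope sample (float
    index); ``eighth_units`` gives each inter-onset segment's notated
    length in eighth notes, including the final event's duration to the
    repetition end.
    """

    samples: np.ndarray
    onset_idx: np.ndarray
    eighth_units: np.ndarray
    trial_index: int
    repetition_index: int
    start_event: int  # 0, or 8 for a follower's count-in repetition
    fs: float = ENVELOPE_FS


@dataclass
class EnvelopeSeries:
    """Envelope resampled to the melodic event grid (m samples per eighth)."""

    samples: np.ndarray
    m: int
    trial_index: int
    repetition_index: int
    start_event: int

    @property
    def grid_length(self) -> int:
        return len(self.samples)


def extract_envelope(
    recording: EEGRecording,
    spatial_filter: np.ndarray,
    f_duet: float,
    melody: MelodySpec,
    *,
    pad_s: float = PAD_S,
    target_fs: float = ENVELOPE_FS,
    halfwidth_hz: float = NARROWBAND_HALFWIDTH_HZ,
) -> list[RawEnvelope]:
    """Per-repetition amplitude envelopes at the duet rate.

    Processing order: spatial projection -> narrowband zero-phase IIR
    filter -> per-repetition epoching with ``pad_s`` pads -> polyphase
    antialias downsampling to ``target_fs`` -> Hilbert magnitude -> pad
    trimming.  (Projection and filtering commute by linearity; projecting
    first filters one channel instead of all.)
    """
    if not 1.0 <= f_duet <= 4.0:
        raise ValueError(f"duet rate {f_duet:.3f} Hz outside the plausible 1-4 Hz range")
    fs = recording.fs
    course = apply_spatial_filter(recording.data, spatial_filter)
    sos = signal.butter(
        2, [f_duet - halfwidth_hz, f_duet + halfwidth_hz], btype="band", fs=fs, output="sos"
    )
    narrow = signal.sosfiltfilt(sos, course)

    down = int(round(fs / target_fs))
    if not math.isclose(fs / down, target_fs):
        raise ValueError(f"fs {fs} is not an integer multiple of target_fs {target_fs}")
    pad = int(round(pad_s * fs))
    pad_ds = int(round(pad_s * target_fs))
    positions = [float(p) for p in melody.beat_positions()]

    out: list[RawEnvelope] = []
    n_dropped = 0
    for _, win in recording.rep_windows.iterrows():
        start, stop = int(win["start_sample"]), int(win["stop_sample"])
        t_i, r_i = int(win["trial_index"]), int(win["repetition_index"])
        if start - pad < 0 or stop + pad > recording.n_samples:
            n_dropped += 1
            continue
        seg = narrow[start - pad : stop + pad]
        seg_ds = signal.resample_poly(seg, 1, down)  # FIR antialiasing polyphase
        env = np.abs(signal.hilbert(seg_ds))
        env = env[pad_ds : len(env) - pad_ds]

        mask = (recording.anchors["trial_index"] == t_i) & (
            recording.anchors["repetition_index"] == r_i
        )
        rep_anchors = recording.anchors[mask].sort_values("event_index")
        onset_idx = (rep_anchors["sample"].to_numpy() - start) / down
        nominal = rep_anchors["nominal_event_index"].to_numpy()
        start_event = int(nominal[0]) if len(nominal) and nominal[0] == COUNT_IN_EVENTS else 0

        # notated eighth-note units per segment, using template positions for
        # matched tones; the final segment runs to the repetition end
        units = []
        for k in range(len(nominal)):
            p0 = positions[nominal[k]] if nominal[k] >= 0 else None
            if k + 1 < len(nominal):
                p1 = positions[nominal[k + 1]] if nominal[k + 1] >= 0 else None
            else:
                p1 = float(melody.total_beats)
            if p0 is None or p1 is None:
                units.append(np.nan)  # inserted tone; such reps are excluded upstream
            else:
                units.append(2.0 * (p1 - p0))
        out.append(RawEnvelope(
            samples=env, onset_idx=onset_idx, eighth_units=np.asarray(units),
            trial_index=t_i, repetition_index=r_i, start_event=start_event,
        ))
    if n_dropped:
        logger.warning("%d repetition(s) dropped: padded epoch extends beyond recording", n_dropped)
    return out


def min_grid_density(envelopes: list[RawEnvelope]) -> int:
    """Minimum eighth-note-equivalent inter-onset sample count (grid ``m``)."""
    best = np.inf
    for env in envelopes:
        seg_samples = np.diff(np.append(env.onset_idx, len(env.samples)))
        with np.errstate(invalid="ignore"):
            per_eighth = seg_samples / env.eighth_units
        best = min(best, np.nanmin(per_eighth))
    m = int(np.floor(best))
    if m < 4:
        raise ValueError(f"grid too coarse: m = {m} samples per eighth note")
    return m


def event_resample(
    envelope: RawEnvelope, melody: MelodySpec, m: int | None = None
) -> EnvelopeSeries:
    """Warp an envelope onto the melodic event grid with PCHIP interpolation.

    Each inter-onset segment maps to ``m x (eighth units)`` grid samples;
    segment start values are reproduced exactly (PCHIP interpolates through
    its knots) and linear data stay linear.  Total grid length is ``64 m``
    for a full repetition.
    """
    if m is None:
        m = min_grid_density([envelope])
    if len(envelope.onset_idx) < 2:
        raise ValueError("need at least 2 onsets to resample")
    x = np.arange(len(envelope.samples), dtype=float)
    pchip = interpolate.PchipInterpolator(x, envelope.samples, extrapolate=True)
    bounds = np.append(envelope.onset_idx, float(len(envelope.samples)))
    pieces = []
    for k in range(len(envelope.onset_idx)):
        n_pts = int(round(m * envelope.eighth_units[k]))
        # half-open segment: include the start knot, stop short of the next
        q = np.linspace(bounds[k], bounds[k + 1], n_pts, endpoint=False)
        pieces.append(pchip(q))
    samples = np.concatenate(pieces)
    return EnvelopeSeries(
        samples=samples, m=m,
        trial_index=envelope.trial_index,
        repetition_index=envelope.repetition_index,
        start_event=envelope.start_event,
    )


def fisher_z(r: float | np.ndarray) -> np.ndarray:
    """Fisher r-to-z with clipping at |r| -> 1 (flagged by the caller)."""
    return np.clip(np.arctanh(np.clip(r, -0.999999, 0.999999)), -Z_CLIP, Z_CLIP)


def fisher_z_mean(r_values: np.ndarray) -> float:
    """Mean correlation on the Fisher-z scale, back-transformed."""
    return float(np.tanh(np.mean(fisher_z(np.asarray(r_values, float)))))


def aec(
    env_leader: EnvelopeSeries,
    env_follower: EnvelopeSeries,
    *,
    skip_count_in: bool | None = None,
) -> float:
    """Pearson AEC of two grid-conformal envelopes for one repetition.

    For a trial's first repetition only the samples at/after the 9th
    tone's grid anchor enter (both partners are playing from there).  When
    one series already starts at the 9th tone the other is trimmed to
    match.
    """
    a, b = env_leader, env_follower
    if a.m != b.m:
        raise ValueError("envelopes are on different grids (m mismatch)")
    grid_count_in = 2 * COUNT_IN_EVENTS * a.m  # 8 quarters = 16 eighth units

    def effective(series: EnvelopeSeries) -> np.ndarray:
        start = 0
        if series.start_event == 0 and (
            skip_count_in
            or (skip_count_in is None and (a.start_event > 0 or b.start_event > 0))
        ):
            start = grid_count_in
        return series.samples[start:]

    xa, xb = effective(a), effective(b)
    n = min(len(xa), len(xb))
    xa, xb = xa[-n:], xb[-n:]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("zero-variance envelope")
    return float(stats.pearsonr(xa, xb)[0])


def condition_aec(
    leader_series: list[EnvelopeSeries],
    follower_series: list[EnvelopeSeries],
) -> dict:
    """Per-repetition AECs Fisher-z averaged within one condition.

    Series are matched by repetition index; repetitions present on only
    one side (e.g. excluded for pitch errors) are skipped.
    """
    by_rep_l = {s.repetition_index: s for s in leader_series}
    by_rep_f = {s.repetition_index: s for s in follower_series}
    common = sorted(set(by_rep_l) & set(by_rep_f))
    rs, skipped = [], 0
    for rep in common:
        try:
            rs.append(aec(by_rep_l[rep], by_rep_f[rep]))
        except ValueError:
            skipped += 1
    if skipped:
        logger.warning("%d repetition(s) skipped (zero-variance envelope)", skipped)
    if not rs:
        raise ValueError("no repetitions with a defined AEC")
    rs = np.asarray(rs)
    zbar = float(np.mean(fisher_z(rs)))
    return {
        "r_per_repetition": rs,
        "fisher_z_mean": zbar,
        "r_mean": float(np.tanh(zbar)),
        "n_repetitions": len(rs),
    }


def surrogate_aecs(
    envelopes_by_pair: dict[int, dict[str, list[RawEnvelope]]],
    melody: MelodySpec,
) -> dict[int, float]:
    """Chance-level AEC per leader from re-paired (surrogate) partners.

    ``envelopes_by_pair[pair_id]`` holds raw (un-resampled) envelopes for
    ``"Leader"`` and ``"Follower"`` of one condition.  Each leader is
    re-paired with every other pair's follower; for each surrogate pairing
    both envelope sets are resampled to the pairing's common grid (the
    minimum ``m`` across the two members) and corresponding repetitions
    correlated.  Returns the Fisher-z mean surrogate correlation per pair,
    back-transformed.
    """
    pair_ids = sorted(envelopes_by_pair)
    if len(pair_ids) < 3:
        raise ValueError("need at least 3 pairs for a surrogate distribution")
    m_of = {
        (pid, role): min_grid_density(envelopes_by_pair[pid][role])
        for pid in pair_ids
        for role in ("Leader", "Follower")
    }
    out: dict[int, float] = {}
    for pid in pair_ids:
        zs = []
        leader_envs = envelopes_by_pair[pid]["Leader"]
        for other in pair_ids:
            if other == pid:
                continue
            follower_envs = envelopes_by_pair[other]["Follower"]
            m = min(m_of[(pid, "Leader")], m_of[(other, "Follower")])
            ls = [event_resample(e, melody, m) for e in leader_envs]
            fs_ = [event_resample(e, melody, m) for e in follower_envs]
            n_l, n_f = len(ls), len(fs_)
            if n_l != n_f:
                warnings.warn(
                    "surrogate members have different repetition counts; "
                    "correlating the repetitions present on both sides",
                    RuntimeWarning,
                    stacklevel=2,
                )
            res = condition_aec(ls, fs_)
            zs.append(res["fisher_z_mean"])
        out[pid] = float(np.tanh(np.mean(zs)))
    return out


def binomial_comparison(
    observed: np.ndarray, surrogate: np.ndarray
) -> dict[str, float]:
    """Exact one-sided binomial test of observed vs surrogate-mean AECs.

    Success = observed exceeds the pair's surrogate mean (ties count as
    failures); under the null each pair succeeds with probability 1/2, so
    the tail p is ``sum_{i>=k} C(n,i) / 2^n``.
    """
    obs = np.asarray(observed, float)
    sur = np.asarray(surrogate, float)
    if obs.shape != sur.shape or obs.size == 0:
        raise ValueError("observed and surrogate must be equal-length, non-empty")
    k = int(np.sum(obs > sur))
    n = obs.size
    p = float(stats.binomtest(k, n, p=0.5, alternative="greater").pvalue)
    return {"k": k, "n": n, "p": p}
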