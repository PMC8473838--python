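"""Synthetic duet behavior and dual-brain EEG with known ground truth.

The generator exists so every downstream stage (error filtering, asynchrony
metrics, frequency-tagged spectra, SSD, envelope correlations) can be tested
by parameter recovery.  Two performers are modelled as coupled timekeepers:

* each performer has a spontaneous quarter-note period ``T`` (their natural
  oscillator frequency, here 1000/T Hz);
* beat times follow a linear phase-correction recursion — the follower
  shifts each beat by ``alpha`` times the current leader-follower beat
  asynchrony, the leader optionally corrects with gain ``beta``;
* tone onsets are read off the latent beat grid: on-beat events at beat
  times, off-beat eighths at the midpoint of their beat interval, half
  notes spanning two beats (one silent).

With zero noise the steady-state leader-minus-follower asynchrony equals
``(T_L - T_F) / (alpha + beta)`` exactly: a slower leader (larger period)
lags by a constant offset proportional to the detuning.

EEG for each brain is a fronto-central oscillatory source at the pair's
duet beat frequency whose slow amplitude envelope is a mixture of a shared
and a private Gaussian process (``sqrt(rho)*shared + sqrt(1-rho)*private``,
mapped through a softplus to keep it positive and smooth), embedded in 1/f
background plus white sensor noise.  ``rho_envelope`` is therefore the
ground-truth inter-brain envelope correlation the pipeline should recover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .data import EEGRecording, PerformanceTrial
from .melody import COUNT_IN_EVENTS, MelodySpec, make_melody_spec

__all__ = [
    "TimingSimConfig",
    "EEGSimConfig",
    "CohortConfig",
    "PairData",
    "DEFAULT_MONTAGE",
    "default_topography",
    "simulate_duet_timing",
    "simulate_solo_timing",
    "inject_pitch_errors",
    "simulate_duet_eeg",
    "simulate_solo_eeg",
    "simulate_pair",
    "iter_cohort",
    "mean_beat_period_ms",
]

#: default 24-channel 10-20 montage (FCz reference, not recorded); includes
#: the fronto-central ROI channels FC1, FC2, Fz, Cz.
DEFAULT_MONTAGE = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FC2", "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2", "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "Oz",
]

# relative source strength per channel for the duet-rate source (smooth
# fronto-central maximum) and for the optional occipital alpha distractor
_FRONTOCENTRAL_WEIGHTS = {
    "Fz": 1.0, "Cz": 1.0, "FC1": 0.95, "FC2": 0.95,
    "F3": 0.6, "F4": 0.6, "C3": 0.6, "C4": 0.6,
    "Fp1": 0.3, "Fp2": 0.3, "F7": 0.25, "F8": 0.25,
    "T7": 0.2, "T8": 0.2, "CP1": 0.45, "CP2": 0.45,
    "Pz": 0.3, "P3": 0.2, "P4": 0.2, "P7": 0.1, "P8": 0.1,
    "O1": 0.05, "O2": 0.05, "Oz": 0.05,
}
_OCCIPITAL_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "Oz": 0.95, "P7": 0.5, "P8": 0.5,
    "P3": 0.55, "P4": 0.55, "Pz": 0.6, "CP1": 0.25, "CP2": 0.25,
    "T7": 0.1, "T8": 0.1, "C3": 0.1, "C4": 0.1, "Cz": 0.1,
}


def default_topography(ch_names: list[str] | None = None) -> np.ndarray:
    """Unit-norm fronto-central source topography over the montage."""
    ch_names = list(ch_names or DEFAULT_MONTAGE)
    w = np.array([_FRONTOCENTRAL_WEIGHTS.get(c, 0.1) for c in ch_names], float)
    return w / np.linalg.norm(w)


def _occipital_topography(ch_names: list[str]) -> np.ndarray:
    w = np.array([_OCCIPITAL_WEIGHTS.get(c, 0.05) for c in ch_names], float)
    return w / np.linalg.norm(w)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class TimingSimConfig:
    """Parameters of the coupled-timekeeper duet timing model.

    Periods are quarter-note beat periods in milliseconds; ``alpha`` and
    ``beta`` are the follower's and leader's phase-correction gains (the
    recursion is contractive for ``0 < alpha + beta < 2``).  Timekeeper
    noise perturbs the latent beat grid; motor noise perturbs emitted
    onsets only.
    """

    t_leader_ms: float = 500.0
    t_follower_ms: float = 520.0
    alpha: float = 0.5
    beta: float = 0.0
    sigma_timekeeper_ms: float = 10.0
    sigma_motor_ms: float = 4.0
    n_repetitions: int = 24
    repetitions_per_trial: int = 4
    p_pitch_error: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name, t in (("t_leader_ms", self.t_leader_ms), ("t_follower_ms", self.t_follower_ms)):
            if not 200.0 <= t <= 1200.0:
                raise ValueError(f"{name}={t} outside the plausible 200-1200 ms range")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("phase-correction gains must be non-negative")
        if self.alpha > 2 or self.beta > 2:
            raise ValueError("phase-correction gains above 2 are outside the modelled range")
        if not 0.0 <= self.p_pitch_error <= 1.0:
            raise ValueError("p_pitch_error must be a probability")
        if self.sigma_timekeeper_ms < 0 or self.sigma_motor_ms < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class EEGSimConfig:
    """Parameters of the dual-brain EEG generator."""

    fs: float = 500.0
    n_channels: int = 24
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    topography: np.ndarray | None = None     # unit-norm; default fronto-central
    rho_envelope: float = 0.4                # ground-truth inter-brain envelope correlation
    snr_db: float = 10.0                     # source vs background power at the duet rate
    distractor_alpha: bool = False           # add an occipital 10 Hz source
    env_cutoff_hz: float = 0.15              # bandwidth of the slow envelope processes
    env_mean: float = 1.0
    env_depth: float = 0.6
    background_rms: float = 1.0              # per-channel 1/f background RMS
    sensor_noise_rms: float = 0.3            # per-channel white noise RMS
    pad_s: float = 3.0                       # silence+noise padding around the performance
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if not 0.0 <= self.rho_envelope <= 1.0:
            raise ValueError("rho_envelope must lie in [0, 1]")
        if self.topography is not None:
            topo = np.asarray(self.topography, float)
            if topo.shape != (self.n_channels,):
                raise ValueError("topography must have one weight per channel")
            if not math.isclose(np.linalg.norm(topo), 1.0, rel_tol=1e-6):
                raise ValueError("topography must have unit norm")
            self.topography = topo


# --------------------------------------------------------------------------
# duet / solo timing
# --------------------------------------------------------------------------

def _beat_grids(
    n_beats: int,
    cfg: TimingSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent beat times (ms, trial-relative) for leader and follower.

    Both grids have ``n_beats + 1`` entries so the final event's end time
    exists.  The follower's grid shadows the leader's through the count-in
    (beats 0..8) and is phase-coupled from beat 8 onward.
    """
    t_l, t_f = cfg.t_leader_ms, cfg.t_follower_ms
    eta_l = rng.normal(0.0, cfg.sigma_timekeeper_ms, n_beats)
    eta_f = rng.normal(0.0, cfg.sigma_timekeeper_ms, n_beats)

    b_l = np.empty(n_beats + 1)
    b_f = np.empty(n_beats + 1)
    b_l[0] = b_f[0] = 0.0
    for k in range(n_beats):
        asyn = b_l[k] - b_f[k]
        b_l[k + 1] = b_l[k] + t_l + eta_l[k] - cfg.beta * asyn
        if k < COUNT_IN_EVENTS:
            # follower listens to the count-in: their timekeeper entrains
            # passively to the leader's beats before they start playing
            b_f[k + 1] = b_l[k + 1]
        else:
            b_f[k + 1] = b_f[k] + t_f + eta_f[k] + cfg.alpha * asyn
    return b_l, b_f


def _events_from_grid(
    melody: MelodySpec,
    grid: np.ndarray,
    rep: int,
    motor_noise: np.ndarray,
    skip_first: int = 0,
) -> pd.DataFrame:
    """Emit one repetition's onsets from a trial-relative beat grid."""
    beats_per_rep = int(melody.total_beats)
    positions = melody.beat_positions()
    rows = []
    for i, (ev, pos) in enumerate(zip(melody.events, positions)):
        if i < skip_first:
            continue
        g = Fraction(beats_per_rep * rep) + pos
        if g.denominator == 1:
            t = grid[int(g)]
        else:  # off-beat eighth: midpoint of its beat interval
            lo = int(g)  # floor
            t = 0.5 * (grid[lo] + grid[lo + 1])
        rows.append(
            dict(
                event_index=i - skip_first,
                nominal_event_index=i,
                nominal_pitch=ev.pitch,
                played_pitch=ev.pitch,
                onset_ms=t + motor_noise[i],
                beat_value=float(ev.beat_value),
                is_on_beat=ev.is_on_beat,
                matched_event_index=-1,
            )
        )
    return pd.DataFrame(rows)


def simulate_duet_timing(
    melody: MelodySpec,
    cfg: TimingSimConfig,
    *,
    rng: np.random.Generator | None = None,
    pair_id: int = 0,
    condition: str = "First-Leader",
    leader_id: str = "L",
    follower_id: str = "F",
    start_ms: float = 3000.0,
    inter_trial_gap_ms: float = 3000.0,
) -> tuple[list[PerformanceTrial], list[PerformanceTrial]]:
    """Simulate coupled leader/follower onset streams for one duet condition.

    Returns one :class:`PerformanceTrial` per melody repetition and
    performer, on a common condition timeline (milliseconds).  The follower
    is silent for the count-in (first ``COUNT_IN_EVENTS`` tones) of each
    trial's first repetition and plays in full unison afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    detuned = not math.isclose(cfg.t_leader_ms, cfg.t_follower_ms)
    if cfg.alpha == 0 and cfg.beta == 0 and detuned and cfg.n_repetitions > 1:
        warnings.warn(
            "alpha=beta=0 with detuned periods: leader-follower drift is unbounded",
            RuntimeWarning,
            stacklevel=2,
        )

    beats_per_rep = int(melody.total_beats)
    n_events = melody.n_events
    leader_trials: list[PerformanceTrial] = []
    follower_trials: list[PerformanceTrial] = []

    reps_left = cfg.n_repetitions
    trial_index = 0
    offset = start_ms
    rep_global = 0
    while reps_left > 0:
        reps_in_trial = min(cfg.repetitions_per_trial, reps_left)
        n_beats = beats_per_rep * reps_in_trial
        b_l, b_f = _beat_grids(n_beats, cfg, rng)
        for r in range(reps_in_trial):
            noise_l = rng.normal(0.0, cfg.sigma_motor_ms, n_events)
            noise_f = rng.normal(0.0, cfg.sigma_motor_ms, n_events)
            skip = COUNT_IN_EVENTS if r == 0 else 0
            ev_l = _events_from_grid(melody, b_l, r, noise_l)
            ev_f = _events_from_grid(melody, b_f, r, noise_f, skip_first=skip)
            for ev in (ev_l, ev_f):
                ev["onset_ms"] += offset
            end_l = offset + b_l[beats_per_rep * (r + 1)]
            end_f = offset + b_f[beats_per_rep * (r + 1)]
            common = dict(pair_id=pair_id, condition=condition,
                          trial_index=trial_index, repetition_index=rep_global)
            leader_trials.append(PerformanceTrial(
                performer_id=leader_id, role="Leader", events=ev_l, end_ms=end_l, **common))
            follower_trials.append(PerformanceTrial(
                performer_id=follower_id, role="Follower", events=ev_f, end_ms=end_f, **common))
            rep_global += 1
        offset += b_l[n_beats] + inter_trial_gap_ms
        reps_left -= reps_in_trial
        trial_index += 1
    return leader_trials, follower_trials


def simulate_solo_timing(
    melody: MelodySpec,
    period_ms: float,
    *,
    sigma_timekeeper_ms: float = 10.0,
    sigma_motor_ms: float = 4.0,
    n_repetitions: int = 12,
    repetitions_per_trial: int = 4,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    pair_id: int = 0,
    performer_id: str = "S",
    start_ms: float = 3000.0,
    inter_trial_gap_ms: float = 3000.0,
) -> list[PerformanceTrial]:
    """Simulate one performer's self-paced (spontaneous-rate) repetitions."""
    cfg = TimingSimConfig(
        t_leader_ms=period_ms, t_follower_ms=period_ms, alpha=0.0, beta=0.0,
        sigma_timekeeper_ms=sigma_timekeeper_ms, sigma_motor_ms=sigma_motor_ms,
        n_repetitions=n_repetitions, repetitions_per_trial=repetitions_per_trial,
        seed=seed,
    )
    leader, _ = simulate_duet_timing(
        melody, cfg, rng=rng, pair_id=pair_id, condition="Solo",
        leader_id=performer_id, follower_id="_unused",
        start_ms=start_ms, inter_trial_gap_ms=inter_trial_gap_ms,
    )
    return [replace(t, role="Leader") for t in leader]


def inject_pitch_errors(
    trials: list[PerformanceTrial],
    p: float,
    rng: np.random.Generator | None = None,
    *,
    seed: int = 0,
) -> list[PerformanceTrial]:
    """Corrupt repetitions with added or deleted tones, with probability ``p``.

    Each corrupted repetition receives exactly one insertion (a random
    melody pitch placed between two existing onsets) or one deletion, chosen
    with equal probability; the ground-truth label is stored in
    ``injected_error`` so the downstream exclusion filter can be validated.
    ``p = 0`` returns the input trials unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if p == 0.0:
        return list(trials)
    if rng is None:
        rng = np.random.default_rng(seed)
    pitch_pool = sorted({int(t) for tr in trials for t in tr.events["nominal_pitch"] if t >= 0})
    out = []
    for tr in trials:
        if rng.random() >= p:
            out.append(tr)
            continue
        ev = tr.events.copy().reset_index(drop=True)
        if rng.random() < 0.5 and len(ev) > 2:  # deletion
            k = int(rng.integers(0, len(ev)))
            ev = ev.drop(index=k).reset_index(drop=True)
            label = "deletion"
        else:  # insertion between two existing onsets
            k = int(rng.integers(0, len(ev) - 1))
            onset = 0.5 * (ev.loc[k, "onset_ms"] + ev.loc[k + 1, "onset_ms"])
            row = dict(
                event_index=-1, nominal_event_index=-1, nominal_pitch=-1,
                played_pitch=int(rng.choice(pitch_pool)), onset_ms=onset,
                beat_value=np.nan, is_on_beat=False, matched_event_index=-1,
            )
            ev = pd.concat(
                [ev.iloc[: k + 1], pd.DataFrame([row]), ev.iloc[k + 1:]],
                ignore_index=True,
            )
            label = "insertion"
        ev["event_index"] = np.arange(len(ev))
        out.append(tr.with_events(ev, injected_error=label))
    return out


def mean_beat_period_ms(trials: list[PerformanceTrial], melody: MelodySpec) -> float:
    """Mean quarter-note beat period implied by repetition durations."""
    beats = float(melody.total_beats)
    durs = []
    for tr in trials:
        if tr.end_ms is None or tr.n_events == 0:
            continue
        start = tr.onsets_ms[0]
        # follower first repetitions start at the 9th tone (beat 8)
        first_nominal = int(tr.events["nominal_event_index"].iloc[0])
        offset_beats = 8.0 if first_nominal == COUNT_IN_EVENTS else 0.0
        durs.append((tr.end_ms - start) / (beats - offset_beats))
    if not durs:
        raise ValueError("no usable repetitions to estimate the beat period")
    return float(np.mean(durs))


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

def _slow_process(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance low-pass Gaussian process (the envelope driver).

    Synthesized in the frequency domain (flat passband, 4th-order
    Butterworth-magnitude rolloff above ``cutoff_hz``) so the process is
    stationary with a Gaussian marginal -- a time-domain IIR pass at such a
    low normalized cutoff leaves edge transients that distort the scale.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(1.0 + (freqs / cutoff_hz) ** 8)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _one_over_f_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectrum ~ 1/f**exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    y = np.fft.irfft(spec, n=n)
    return y / y.std()


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _narrowband_var(x: np.ndarray, fs: float, f0: float, half_bw: float = 0.183) -> float:
    sos = signal.butter(2, [f0 - half_bw, f0 + half_bw], btype="band", fs=fs, output="sos")
    return float(np.var(signal.sosfiltfilt(sos, x)))


def _brain_signal(
    n: int,
    fs: float,
    f0: float,
    envelope: np.ndarray,
    topo: np.ndarray,
    cfg: EEGSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One brain's channels x samples array: source + 1/f + sensor noise."""
    n_ch = cfg.n_channels
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2 * np.pi)
    source = envelope * np.cos(2 * np.pi * f0 * t + phase)

    if cfg.background_rms > 0:
        background = np.stack(
            [cfg.background_rms * _one_over_f_noise(n, fs, 1.0, rng) for _ in range(n_ch)]
        )
    else:
        background = np.zeros((n_ch, n))
    if cfg.sensor_noise_rms > 0:
        background += cfg.sensor_noise_rms * rng.standard_normal((n_ch, n))

    # calibrate source gain: snr_db is the power ratio, within the duet-rate
    # narrowband, between the source and the topography-projected background
    if cfg.background_rms > 0 or cfg.sensor_noise_rms > 0:
        var_bg = _narrowband_var(topo @ background, fs, f0)
        gain = math.sqrt(var_bg * 10.0 ** (cfg.snr_db / 10.0) / np.var(source))
    else:
        gain = 1.0

    data = np.outer(topo, gain * source) + background

    if cfg.distractor_alpha:
        topo_d = _occipital_topography(cfg.channel_names)
        env_d = _softplus(cfg.env_mean + cfg.env_depth * _slow_process(n, fs, cfg.env_cutoff_hz, rng))
        src_d = env_d * np.cos(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        data += np.outer(topo_d, gain * src_d)
    return data


def _anchor_tables(
    trials: list[PerformanceTrial], fs: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    anchor_rows, window_rows = [], []
    for tr in trials:
        for _, row in tr.events.iterrows():
            anchor_rows.append(dict(
                trial_index=tr.trial_index, repetition_index=tr.repetition_index,
                event_index=int(row["event_index"]),
                nominal_event_index=int(row["nominal_event_index"]),
                sample=int(round(row["onset_ms"] * fs / 1000.0)),
            ))
        window_rows.append(dict(
            trial_index=tr.trial_index, repetition_index=tr.repetition_index,
            start_sample=int(round(tr.onsets_ms[0] * fs / 1000.0)),
            stop_sample=int(round((tr.end_ms if tr.end_ms is not None else tr.onsets_ms[-1]) * fs / 1000.0)),
        ))
    return pd.DataFrame(anchor_rows), pd.DataFrame(window_rows)


def simulate_duet_eeg(
    leader_trials: list[PerformanceTrial],
    follower_trials: list[PerformanceTrial],
    cfg: EEGSimConfig,
    *,
    melody: MelodySpec | None = None,
    f_duet: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EEGRecording, EEGRecording]:
    """Simulate the two partners' EEG for one duet condition.

    Both recordings live on the shared condition timeline of the timing
    simulation; the two duet-rate sources share an amplitude envelope
    component with mixing weight ``sqrt(rho_envelope)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    melody = melody or make_melody_spec()
    if f_duet is None:
        period = 0.5 * (
            mean_beat_period_ms(leader_trials, melody)
            + mean_beat_period_ms(follower_trials, melody)
        )
        f_duet = 1000.0 / period
    if f_duet >= cfg.fs / 2:
        raise ValueError(f"duet rate {f_duet:.2f} Hz at or above Nyquist ({cfg.fs / 2} Hz)")

    t_end = max(
        max(tr.end_ms or tr.onsets_ms[-1] for tr in leader_trials),
        max(tr.end_ms or tr.onsets_ms[-1] for tr in follower_trials),
    )
    n = int(round((t_end / 1000.0 + cfg.pad_s) * cfg.fs))
    topo = cfg.topography if cfg.topography is not None else default_topography(cfg.channel_names)

    shared = _slow_process(n, cfg.fs, cfg.env_cutoff_hz, rng)
    rho = cfg.rho_envelope
    recs = []
    for trials in (leader_trials, follower_trials):
        private = _slow_process(n, cfg.fs, cfg.env_cutoff_hz, rng)
        z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * private
        envelope = _softplus(cfg.env_mean + cfg.env_depth * z)
        data = _brain_signal(n, cfg.fs, f_duet, envelope, topo, cfg, rng)
        anchors, windows = _anchor_tables(trials, cfg.fs)
        tr0 = trials[0]
        recs.append(EEGRecording(
            data=data, fs=cfg.fs, ch_names=list(cfg.channel_names),
            anchors=anchors, rep_windows=windows,
            pair_id=tr0.pair_id, performer_id=tr0.performer_id, condition=tr0.condition,
            source_envelope=envelope,
        ))
    return recs[0], recs[1]


def simulate_solo_eeg(
    trials: list[PerformanceTrial],
    cfg: EEGSimConfig,
    *,
    melody: MelodySpec | None = None,
    f_solo: float | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Simulate one performer's solo EEG (used to fit SSD spatial filters)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    melody = melody or make_melody_spec()
    if f_solo is None:
        f_solo = 1000.0 / mean_beat_period_ms(trials, melody)
    if f_solo >= cfg.fs / 2:
        raise ValueError("solo rate at or above Nyquist")
    t_end = max(tr.end_ms or tr.onsets_ms[-1] for tr in trials)
    n = int(round((t_end / 1000.0 + cfg.pad_s) * cfg.fs))
    topo = cfg.topography if cfg.topography is not None else default_topography(cfg.channel_names)
    envelope = _softplus(cfg.env_mean + cfg.env_depth * _slow_process(n, cfg.fs, cfg.env_cutoff_hz, rng))
    data = _brain_signal(n, cfg.fs, f_solo, envelope, topo, cfg, rng)
    anchors, windows = _anchor_tables(trials, cfg.fs)
    tr0 = trials[0]
    return EEGRecording(
        data=data, fs=cfg.fs, ch_names=list(cfg.channel_names),
        anchors=anchors, rep_windows=windows,
        pair_id=tr0.pair_id, performer_id=tr0.performer_id, condition="Solo",
        source_envelope=envelope,
    )


# --------------------------------------------------------------------------
# cohort-level generation
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-level defaults for simulated cohorts of duet pairs.

    Spontaneous beat periods are drawn uniformly over 380-580 ms, matching
    the observed spread of self-paced piano tempi (pair averages roughly
    300-600 ms, typical partner detuning of order 70 ms).
    """

    n_pairs: int = 20
    n_duet_repetitions: int = 24
    repetitions_per_trial: int = 4
    n_solo_repetitions: int = 12
    solo_period_range_ms: tuple[float, float] = (380.0, 580.0)
    alpha: float = 0.5
    beta: float = 0.0
    sigma_timekeeper_ms: float = 10.0
    sigma_motor_ms: float = 4.0
    p_pitch_error: float = 0.04
    conditions: tuple[str, ...] = ("First-Leader", "Second-Leader")
    simulate_eeg: bool = True
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    seed: int = 0


@dataclass
class PairData:
    """All simulated material for one duet pair."""

    pair_id: int
    performer_a: str
    performer_b: str
    solo_period_ms: dict          # performer -> ground-truth beat period
    solo_trials: dict             # performer -> list[PerformanceTrial]
    duet_trials: dict             # condition -> {"Leader": [...], "Follower": [...]}
    leader_of: dict               # condition -> performer id
    solo_eeg: dict | None = None  # performer -> EEGRecording
    duet_eeg: dict | None = None  # condition -> {performer: EEGRecording}


def simulate_pair(
    pair_id: int,
    cfg: CohortConfig,
    seed: int,
    *,
    melody: MelodySpec | None = None,
) -> PairData:
    """Simulate one pair: solo trials for both partners plus both duet
    leader-order conditions, with EEG if ``cfg.simulate_eeg``."""
    melody = melody or make_melody_spec()
    rng = np.random.default_rng(seed)
    pa, pb = f"p{pair_id:02d}A", f"p{pair_id:02d}B"
    lo, hi = cfg.solo_period_range_ms
    periods = {pa: float(rng.uniform(lo, hi)), pb: float(rng.uniform(lo, hi))}

    solo_trials, solo_eeg = {}, {}
    for perf in (pa, pb):
        trials = simulate_solo_timing(
            melody, periods[perf],
            sigma_timekeeper_ms=cfg.sigma_timekeeper_ms,
            sigma_motor_ms=cfg.sigma_motor_ms,
            n_repetitions=cfg.n_solo_repetitions,
            repetitions_per_trial=cfg.repetitions_per_trial,
            rng=rng, pair_id=pair_id, performer_id=perf,
        )
        trials = inject_pitch_errors(trials, cfg.p_pitch_error, rng)
        solo_trials[perf] = trials
        if cfg.simulate_eeg:
            solo_eeg[perf] = simulate_solo_eeg(
                [t for t in trials if t.injected_error is None],
                cfg.eeg, melody=melody, rng=rng,
            )

    duet_trials, duet_eeg, leader_of = {}, {}, {}
    for ci, condition in enumerate(cfg.conditions):
        leader, follower = (pa, pb) if ci % 2 == 0 else (pb, pa)
        leader_of[condition] = leader
        tcfg = TimingSimConfig(
            t_leader_ms=periods[leader], t_follower_ms=periods[follower],
            alpha=cfg.alpha, beta=cfg.beta,
            sigma_timekeeper_ms=cfg.sigma_timekeeper_ms,
            sigma_motor_ms=cfg.sigma_motor_ms,
            n_repetitions=cfg.n_duet_repetitions,
            repetitions_per_trial=cfg.repetitions_per_trial,
            p_pitch_error=cfg.p_pitch_error,
        )
        lt, ft = simulate_duet_timing(
            melody, tcfg, rng=rng, pair_id=pair_id, condition=condition,
            leader_id=leader, follower_id=follower,
        )
        lt = inject_pitch_errors(lt, cfg.p_pitch_error, rng)
        ft = inject_pitch_errors(ft, cfg.p_pitch_error, rng)
        duet_trials[condition] = {"Leader": lt, "Follower": ft}
        if cfg.simulate_eeg:
            rec_l, rec_f = simulate_duet_eeg(lt, ft, cfg.eeg, melody=melody, rng=rng)
            duet_eeg[condition] = {leader: rec_l, follower: rec_f}

    return PairData(
        pair_id=pair_id, performer_a=pa, performer_b=pb,
        solo_period_ms=periods, solo_trials=solo_trials,
        duet_trials=duet_trials, leader_of=leader_of,
        solo_eeg=solo_eeg or None, duet_eeg=duet_eeg or None,
    )


def iter_cohort(cfg: CohortConfig, *, melody: MelodySpec | None = None):
    """Yield :class:`PairData` for each pair, one at a time.

    Pairs are generated lazily so EEG arrays for a whole cohort never need
    to be resident simultaneously.  Each pair gets an independent child
    seed spawned from ``cfg.seed``, so results are reproducible and
    per-pair independent of cohort size.
    """
    melody = melody or make_melody_spec()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_pairs)
    for pair_id, ss in enumerate(children):
        seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        yield simulate_pair(pair_id, cfg, seed, melody=melody)
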