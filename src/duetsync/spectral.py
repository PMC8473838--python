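"""Frequency-tagged EEG spectra at the duet performance rate.

The entrainment measure is a noise-normalized log power spectrum: each
9-second melody epoch is Hanning-windowed as a single segment and
transformed with an 8192-point FFT (bin spacing 500/8192 = 0.061 Hz), log
power is averaged over epochs, and each bin has the mean of its +-3
neighboring bins subtracted so broadband 1/f background cancels while
narrowband peaks survive.  Spectra from different pairs are made comparable
by extracting a 49-bin (2.99 Hz) window centered on the bin nearest each
pair's duet performance rate; a peak at the duet rate is then tested with a
Wilcoxon signed-rank comparison of the center bin against the mean of its
+-8 neighbors across participants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .data import EEGRecording

__all__ = [
    "SpectralConfig",
    "NormalizedSpectrum",
    "prefilter",
    "epoch_fixed_window",
    "welch_psd",
    "lognormalize",
    "align_to_duet_rate",
    "roi_mean",
    "peak_test",
    "psd_synchrony_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class SpectralConfig:
    fs: float = 500.0
    epoch_s: float = 9.0
    nfft: int = 8192                       # unique power of two giving 0.061 Hz bins
    highpass_hz: float = 0.1
    lowpass_hz: float = 20.0
    fir_order: int = 1000                  # windowed-sinc pre-filter order
    noise_offsets: tuple[int, ...] = (1, 2, 3)   # +- bin offsets for noise normalization
    peak_halfwidth_bins: int = 8
    align_halfwidth_bins: int = 24
    roi: tuple[str, ...] = ("FC1", "FC2", "Cz", "Fz")

    @property
    def window_samples(self) -> int:
        return int(round(self.epoch_s * self.fs))  # 4500 at the defaults

    @property
    def bin_spacing_hz(self) -> float:
        return self.fs / self.nfft

    @property
    def align_window_bins(self) -> int:
        return 2 * self.align_halfwidth_bins + 1

    @property
    def align_window_span_hz(self) -> float:
        return self.align_window_bins * self.bin_spacing_hz

    @property
    def noise_halfwidth_hz(self) -> float:
        return max(self.noise_offsets) * self.bin_spacing_hz


@dataclass
class NormalizedSpectrum:
    """Noise-normalized log power, per channel."""

    freqs_hz: np.ndarray       # bin centers, equally spaced at fs/nfft
    values: np.ndarray         # (n_channels, n_bins)
    ch_names: list[str]
    edge_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def center_bin(self, f_duet: float) -> int:
        """Bin nearest ``f_duet``; exact midpoint ties go to the lower bin."""
        below = int(np.floor(f_duet / (self.freqs_hz[1] - self.freqs_hz[0])))
        below = min(max(below, 0), len(self.freqs_hz) - 2)
        d_lo = f_duet - self.freqs_hz[below]
        d_hi = self.freqs_hz[below + 1] - f_duet
        return below if d_lo <= d_hi else below + 1


def prefilter(recording: EEGRecording, cfg: SpectralConfig) -> EEGRecording:
    """Zero-phase windowed-sinc band limitation (0.1-20 Hz at defaults)."""
    lp = signal.firwin(cfg.fir_order + 1, cfg.lowpass_hz, window="hann", fs=cfg.fs)
    hp = signal.firwin(
        cfg.fir_order + 1, cfg.highpass_hz, window="hann", fs=cfg.fs, pass_zero=False
    )
    data = recording.data
    for taps in (lp, hp):
        data = signal.filtfilt(taps, [1.0], data, axis=-1, padlen=min(3 * len(taps), data.shape[-1] - 1))
    return EEGRecording(
        data=data, fs=recording.fs, ch_names=list(recording.ch_names),
        anchors=recording.anchors, rep_windows=recording.rep_windows,
        pair_id=recording.pair_id, performer_id=recording.performer_id,
        condition=recording.condition,
    )


def epoch_fixed_window(recording: EEGRecording, cfg: SpectralConfig) -> np.ndarray:
    """One fixed-duration epoch per melody repetition.

    Epochs are half-open sample intervals of ``window_samples`` starting at
    each repetition's first sample; repetitions shorter than the window
    simply extend into the beginning of the subsequent repetition (the
    recording is continuous).  A final repetition without enough subsequent
    data is dropped with a warning.  Returns (n_epochs, n_channels, n_samples).
    """
    win = cfg.window_samples
    starts = np.asarray(recording.rep_windows["start_sample"], dtype=int)
    epochs = []
    n_dropped = 0
    for s in starts:
        if s + win > recording.n_samples:
            n_dropped += 1
            continue
        epochs.append(recording.data[:, s : s + win])
    if n_dropped:
        logger.warning(
            "%d repetition(s) dropped: fewer than %d samples remained in the recording",
            n_dropped, win,
        )
    if not epochs:
        raise ValueError("no repetition fits a full analysis window")
    return np.stack(epochs)


def welch_psd(epoch: np.ndarray, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """Single-segment Welch PSD of one epoch (channels x window_samples).

    The whole epoch is one Hanning-windowed segment zero-padded to
    ``nfft``, i.e. a single modified periodogram -- which is what Welch's
    method reduces to when the segment length equals the epoch length.
    """
    if epoch.shape[-1] != cfg.window_samples:
        raise ValueError(
            f"epoch length {epoch.shape[-1]} != required {cfg.window_samples} samples"
        )
    freqs, psd = signal.welch(
        epoch, fs=cfg.fs, window=signal.get_window("hann", cfg.window_samples),
        nperseg=cfg.window_samples, noverlap=0, nfft=cfg.nfft,
        detrend=False, scaling="density", axis=-1,
    )
    return freqs, psd


def lognormalize(
    freqs: np.ndarray,
    mean_log_psd: np.ndarray,
    cfg: SpectralConfig,
    ch_names: list[str] | None = None,
) -> NormalizedSpectrum:
    """Subtract from each log-power bin the mean of its +-1..3 neighbors.

    ``mean_log_psd`` is the epoch-averaged natural-log PSD (channels x
    bins).  Edge bins use the neighbors that exist and are flagged in
    ``edge_bins``.
    """
    x = np.atleast_2d(np.asarray(mean_log_psd, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("log PSD contains non-finite values (zero or negative power?)")
    n_bins = x.shape[1]
    offsets = sorted(cfg.noise_offsets)
    out = np.empty_like(x)
    max_off = max(offsets)
    idx = np.arange(n_bins)
    neighbor_sum = np.zeros_like(x)
    neighbor_cnt = np.zeros(n_bins)
    for off in offsets:
        for sgn in (-1, 1):
            j = idx + sgn * off
            valid = (j >= 0) & (j < n_bins)
            neighbor_sum[:, valid] += x[:, j[valid]]
            neighbor_cnt[valid] += 1
    out = x - neighbor_sum / neighbor_cnt
    edge = idx[(idx < max_off) | (idx >= n_bins - max_off)]
    names = ch_names if ch_names is not None else [f"ch{i}" for i in range(x.shape[0])]
    return NormalizedSpectrum(freqs_hz=freqs, values=out, ch_names=list(names), edge_bins=edge)


def mean_log_psd(epochs: np.ndarray, cfg: SpectralConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch log PSD averaged over epochs: (freqs, channels x bins)."""
    logs = []
    for ep in epochs:
        freqs, psd = welch_psd(ep, cfg)
        if np.any(psd <= 0):
            raise ValueError("non-positive power before log transform")
        logs.append(np.log(psd))
    return freqs, np.mean(logs, axis=0)


def align_to_duet_rate(
    spectrum: NormalizedSpectrum, f_duet: float, cfg: SpectralConfig
) -> np.ndarray:
    """49-bin window (center +- 24 bins) around the bin nearest the duet rate.

    Returns (n_channels, 49); index 24 is the duet-rate bin.
    """
    c = spectrum.center_bin(f_duet)
    h = cfg.align_halfwidth_bins
    n_bins = spectrum.values.shape[1]
    if c - h < 0 or c + h >= n_bins:
        raise ValueError(
            f"duet rate {f_duet:.3f} Hz too close to the spectrum edge "
            f"(center bin {c}, need +-{h} bins)"
        )
    return spectrum.values[:, c - h : c + h + 1]


def roi_mean(
    values: np.ndarray, ch_names: list[str], roi: tuple[str, ...]
) -> np.ndarray:
    """Unweighted mean over ROI channels (case-insensitive name match)."""
    lowered = [c.lower() for c in ch_names]
    missing = [r for r in roi if r.lower() not in lowered]
    if missing:
        raise ValueError(f"ROI channel(s) missing from recording: {missing}")
    idx = [lowered.index(r.lower()) for r in roi]
    return np.asarray(values)[idx].mean(axis=0)


def peak_test(
    aligned: np.ndarray,
    cfg: SpectralConfig,
    method: str = "auto",
    alternative: str = "greater",
) -> dict[str, float]:
    """Wilcoxon signed-rank test of the duet-rate bin against its neighbors.

    ``aligned`` is (n_participants, 49): one rate-aligned spectrum per
    participant.  The paired difference is the center bin minus the mean of
    the 16 bins at offsets +-1..8.  ``method='normal'`` reports the
    normal-approximation z (the convention in the frequency-tagging
    literature); ``method='exact'`` enumerates the exact null, and
    ``'auto'`` uses exact for n <= 25.
    """
    aligned = np.atleast_2d(aligned)
    n_part, n_bins = aligned.shape
    if n_part < 6:
        raise ValueError("need at least 6 participants for the peak test")
    c = n_bins // 2
    h = cfg.peak_halfwidth_bins
    neigh = np.concatenate([aligned[:, c - h : c], aligned[:, c + 1 : c + h + 1]], axis=1)
    diffs = aligned[:, c] - neigh.mean(axis=1)
    if np.all(diffs == 0):
        return {"statistic": 0.0, "z": 0.0, "p": 1.0, "n": n_part, "degenerate": True}
    if method == "auto":
        method = "exact" if n_part <= 25 else "normal"
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_plus - mu) / sigma
    if method == "normal":
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    elif method == "exact":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(diffs, alternative=alternative, method="exact")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": w_plus, "z": float(z), "p": p, "n": n_part, "degenerate": False}


def psd_synchrony_correlation(
    psd_values: np.ndarray, absolute_asynchrony: np.ndarray
) -> dict[str, float]:
    """Pearson correlation of duet-rate PSD with synchronization accuracy.

    Smaller absolute asynchrony = better synchrony, so entrainment that
    aids synchrony shows up as a negative correlation.
    """
    x = np.asarray(psd_values, float)
    y = np.asarray(absolute_asynchrony, float)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x)}


def asynchrony_psd_regression(
    leader_psd: np.ndarray, follower_psd: np.ndarray, absolute_asynchrony: np.ndarray
):
    """OLS predicting duet asynchrony from both partners' duet-rate PSD."""
    from .behavior import duet_rate_regression

    return duet_rate_regression(leader_psd, follower_psd, absolute_asynchrony)
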