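"""Spatio-spectral decomposition (SSD) for oscillation extraction.

SSD finds spatial filters ``w`` maximizing the ratio of band power in a
target frequency band to power in two flanking bands, by solving the
generalized eigenproblem ``S w = lambda N w`` where ``S`` and ``N`` are the
covariances of band-passed and flank-passed data.  Here the target band is
the range of observed self-paced performance rates (1.5-3.5 Hz); filters
are fitted on solo-task EEG and applied to duet EEG, keeping fit and
application data independent.

The component the analysis uses is chosen automatically as a proxy for
visual selection of a fronto-central delta topography: the score is the
eigenvalue (band/flank power ratio) times the fraction of forward-pattern
loading on the fronto-central ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .data import EEGRecording

__all__ = ["SSDResult", "fit_ssd", "select_component", "apply_spatial_filter"]

DEFAULT_BAND = (1.5, 3.5)
DEFAULT_ROI = ("FC1", "FC2", "Cz", "Fz")


@dataclass
class SSDResult:
    filters: np.ndarray       # (n_channels, n_components), columns = w
    patterns: np.ndarray      # forward patterns, column-normalized
    eigenvalues: np.ndarray   # descending band/flank power ratios
    band: tuple[float, float]
    flanks: tuple[tuple[float, float], tuple[float, float]]
    ch_names: list[str]

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]


def _bandpass(data: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (second-order sections)."""
    lo = max(lo, 0.1)  # a 0 Hz band edge is unrealizable; clip just above DC
    sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def fit_ssd(
    recording: EEGRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    flank_width: float = 1.0,
    gap: float = 0.5,
    filter_order: int = 2,
    ridge: float = 1e-6,
) -> SSDResult:
    """Fit SSD spatial filters on a (solo) recording.

    Flanks are ``[band_lo - gap - flank_width, band_lo - gap]`` and
    ``[band_hi + gap, band_hi + gap + flank_width]``; their covariances are
    summed into the noise matrix.  A fixed shrinkage ridge
    (``ridge * trace/dim``) regularizes a near-singular noise covariance,
    with a warning.
    """
    data = recording.data
    if not np.all(np.isfinite(data)):
        raise ValueError("recording contains non-finite samples")
    if data.shape[0] < 2:
        raise ValueError("SSD needs at least 2 channels")
    if data.shape[0] < 4:
        warnings.warn(
            "fewer than 4 channels: spatial filtering has little room to work",
            RuntimeWarning,
            stacklevel=2,
        )
    if recording.duration_s < 60:
        warnings.warn(
            f"recording is only {recording.duration_s:.0f} s; SSD covariances may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    fs = recording.fs
    lo, hi = band
    flank_lo = (lo - gap - flank_width, lo - gap)
    flank_hi = (hi + gap, hi + gap + flank_width)

    x_band = _bandpass(data, fs, lo, hi, filter_order)
    x_noise = (
        _bandpass(data, fs, *flank_lo, order=filter_order)
        + _bandpass(data, fs, *flank_hi, order=filter_order)
    )
    S = np.cov(x_band)
    N = np.cov(x_noise)

    dim = N.shape[0]
    cond = np.linalg.cond(N)
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn(
            "noise covariance is near-singular; applying shrinkage ridge",
            RuntimeWarning,
            stacklevel=2,
        )
        N = N + ridge * np.trace(N) / dim * np.eye(dim)

    eigvals, eigvecs, patterns = ssd_eig(S, N)
    return SSDResult(
        filters=eigvecs, patterns=patterns, eigenvalues=eigvals,
        band=band, flanks=(flank_lo, flank_hi), ch_names=list(recording.ch_names),
    )


def ssd_eig(S: np.ndarray, N: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve ``S w = lambda N w``; eigenpairs sorted by descending lambda.

    Returns (eigenvalues, filters, forward patterns); patterns are
    ``S @ w`` column-normalized.  When ``S = N`` every eigenvalue is 1.
    """
    eigvals, eigvecs = linalg.eigh(S, N)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    patterns = S @ eigvecs
    patterns /= np.linalg.norm(patterns, axis=0, keepdims=True)
    return eigvals, eigvecs, patterns


def apply_spatial_filter(data: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Project channels x samples onto one spatial filter."""
    return np.asarray(w) @ np.asarray(data)


def select_component(
    ssd: SSDResult,
    roi: tuple[str, ...] = DEFAULT_ROI,
    index: int | None = None,
) -> tuple[np.ndarray, int]:
    """Pick the component representing the fronto-central duet-rate source.

    Score = eigenvalue (spectral SNR of the component in the target band)
    x ROI loading fraction of the absolute forward pattern.  Returns a
    unit-norm filter, sign-fixed so the mean ROI pattern loading is
    positive (flipping the sign of all channel data therefore leaves the
    component's output unchanged).  ``index`` overrides the automatic
    choice.
    """
    lowered = [c.lower() for c in ssd.ch_names]
    roi_idx = [lowered.index(r.lower()) for r in roi if r.lower() in lowered]
    if not roi_idx:
        raise ValueError("no ROI channel present in the SSD result")

    abs_pat = np.abs(ssd.patterns)
    roi_frac = abs_pat[roi_idx].sum(axis=0) / abs_pat.sum(axis=0)
    scores = np.clip(ssd.eigenvalues, 0, None) * roi_frac

    if index is None:
        roi_sign = ssd.patterns[roi_idx].mean(axis=0)
        if np.all(roi_sign == 0):
            warnings.warn(
                "no component with nonzero ROI loading; falling back to max eigenvalue",
                RuntimeWarning,
                stacklevel=2,
            )
            index = 0
        else:
            index = int(np.argmax(scores))
    w = ssd.filters[:, index].copy()
    w /= np.linalg.norm(w)
    # sign convention: positive mean forward-pattern loading over the ROI
    pat = ssd.patterns[:, index]
    if pat[roi_idx].mean() < 0:
        w = -w
    return w, index
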