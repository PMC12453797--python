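"""Cleaning and segmentation of raw physiological signals.

The cleaning chain is: outlier masking by z-score thresholding, linear
interpolation of missing samples, and (for EEG only) zero-phase Butterworth
bandpass filtering followed by per-channel z-score standardization.  GSR and
heart-rate channels receive masking + interpolation only, since the 4-45 Hz
band is an EEG convention.  Cleaned channels are then cut into fixed-length,
possibly overlapping analysis windows.

Missing samples are represented as NaN throughout, paired with an explicit
boolean mask where one is carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal as sps


class Modality(str, Enum):
    EEG = "EEG"
    GSR = "GSR"
    HR = "HR"


@dataclass
class RawRecording:
    """One subject/trial's time series for a single modality.

    ``samples`` is channels x time; ``missing_mask`` marks unusable samples
    (True = missing).  ``ratings`` is the optional (valence, arousal) pair on
    the 1-9 self-assessment scale.
    """

    subject_id: str
    trial_id: str
    modality: Modality
    sampling_rate_hz: float
    samples: np.ndarray
    missing_mask: Optional[np.ndarray] = None
    ratings: Optional[tuple[float, float]] = None
    session_period: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.samples)
        else:
            self.missing_mask = np.atleast_2d(np.asarray(self.missing_mask, dtype=bool))
        if self.samples.shape != self.missing_mask.shape:
            raise ValueError("samples and missing_mask must have identical shape")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.modality = Modality(self.modality)
        if self.modality in (Modality.GSR, Modality.HR) and self.n_channels != 1:
            raise ValueError(f"{self.modality.value} recordings must have exactly 1 channel")
        if self.modality is Modality.EEG and self.n_channels < 1:
            raise ValueError("EEG recordings need at least one channel")
        if self.ratings is not None:
            v, a = self.ratings
            if not (1 <= v <= 9 and 1 <= a <= 9):
                raise ValueError("ratings must lie in [1, 9]")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class SignalWindow:
    """A contiguous, gap-free slice of one channel of a recording."""

    values: np.ndarray
    start_sample: int
    channel: int = 0
    source: Optional[RawRecording] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("window must contain at least one sample")
        if self.start_sample < 0:
            raise ValueError("start_sample must be >= 0")
        if np.isnan(self.values).any():
            raise ValueError("window values must contain no missing entries")

    def __len__(self) -> int:
        return self.values.size


def mask_outliers(
    x: np.ndarray, z_thresh: float = 3.0, mask: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mark samples whose |z-score| exceeds ``z_thresh`` as missing.

    The mean and (population) standard deviation are computed over the
    non-missing entries only.  A constant signal (sd = 0) has no outliers by
    convention.  Returns the signal with flagged entries set to NaN plus the
    boolean outlier mask (flagged entries only; pre-existing missing entries
    are not re-flagged).
    """
    x = np.asarray(x, dtype=float).copy()
    if mask is None:
        observed = ~np.isnan(x)
    else:
        observed = ~(np.asarray(mask, dtype=bool) | np.isnan(x))
    if observed.sum() < 2:
        raise ValueError("need at least 2 non-missing samples to estimate spread")
    mu = x[observed].mean()
    sd = x[observed].std()
    out = np.zeros_like(x, dtype=bool)
    if sd > 0:
        z = np.zeros_like(x)
        z[observed] = (x[observed] - mu) / sd
        out = observed & (np.abs(z) > z_thresh)
    x[out] = np.nan
    return x, out


def interpolate_missing(x: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Fill missing samples by linear interpolation between observed neighbours.

    Leading/trailing missing runs take the nearest observed value (the
    behaviour of ``np.interp`` outside the observed support).
    """
    x = np.asarray(x, dtype=float).copy()
    missing = np.isnan(x)
    if mask is not None:
        missing = missing | np.asarray(mask, dtype=bool)
    if missing.all():
        raise ValueError("cannot interpolate an all-missing signal")
    if not missing.any():
        return x
    idx = np.arange(x.size)
    x[missing] = np.interp(idx[missing], idx[~missing], x[~missing])
    return x


def bandpass(
    x: np.ndarray, fs: float, low: float = 4.0, high: float = 45.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, order per pass)."""
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if not 0 < low:
        raise ValueError(f"low cutoff {low} Hz must be positive")
    if not low < high:
        raise ValueError(f"low cutoff {low} Hz must lie below high cutoff {high} Hz")
    if not high < nyq:
        raise ValueError(f"high cutoff {high} Hz violates the Nyquist limit {nyq} Hz")
    if x.size < 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def zscore_channel(x: np.ndarray) -> np.ndarray:
    """Standardize one channel to zero mean, unit (population) sd."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant (degenerate) channel")
    return (x - x.mean()) / sd


def segment_windows(
    x: np.ndarray,
    fs: float,
    window_s: float,
    overlap_frac: float = 0.0,
    channel: int = 0,
    source: Optional[RawRecording] = None,
) -> list[SignalWindow]:
    """Cut a signal into fixed-length windows with fractional overlap.

    Window length W = round(window_s * fs); stride = round(W * (1 - overlap));
    a trailing partial window is discarded.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must span at least 2 samples")
    if x.size < w:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {w}-sample window"
        )
    stride = int(round(w * (1 - overlap_frac)))
    stride = max(stride, 1)
    n_win = (x.size - w) // stride + 1
    return [
        SignalWindow(
            values=x[i * stride : i * stride + w],
            start_sample=i * stride,
            channel=channel,
            source=source,
        )
        for i in range(n_win)
    ]


@dataclass
class PreprocessConfig:
    """Per-modality cleaning and windowing settings.

    Window defaults follow the experiment actually run: 4 s / 50 % overlap for
    EEG, 8 s / 50 % for the slower GSR and heart-rate channels.
    """

    z_thresh: float = 3.0
    eeg_band: tuple[float, float] = (4.0, 45.0)
    filter_order: int = 4
    window_s: dict = field(
        default_factory=lambda: {"EEG": 4.0, "GSR": 8.0, "HR": 8.0}
    )
    overlap_frac: dict = field(
        default_factory=lambda: {"EEG": 0.5, "GSR": 0.5, "HR": 0.5}
    )


def clean_channel(x: np.ndarray, z_thresh: float = 3.0) -> np.ndarray:
    """Outlier masking followed immediately by interpolation (gap-free output)."""
    masked, _ = mask_outliers(x, z_thresh=z_thresh)
    return interpolate_missing(masked)


def preprocess_recording(
    rec: RawRecording, cfg: Optional[PreprocessConfig] = None
) -> list[list[SignalWindow]]:
    """Clean and segment every channel of a recording.

    Returns one list of windows per channel.  EEG channels are additionally
    bandpass filtered and z-scored; GSR/HR are left in physical units so that
    their moment features remain informative.
    """
    cfg = cfg or PreprocessConfig()
    mod = rec.modality.value
    out: list[list[SignalWindow]] = []
    for ch in range(rec.n_channels):
        x = rec.samples[ch].copy()
        x[rec.missing_mask[ch]] = np.nan
        x = clean_channel(x, z_thresh=cfg.z_thresh)
        if rec.modality is Modality.EEG:
            low, high = cfg.eeg_band
            x = bandpass(x, rec.sampling_rate_hz, low, high, cfg.filter_order)
            x = zscore_channel(x)
        out.append(
            segment_windows(
                x,
                rec.sampling_rate_hz,
                cfg.window_s[mod],
                cfg.overlap_frac[mod],
                channel=ch,
                source=rec,
            )
        )
    return out
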