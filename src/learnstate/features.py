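"""Window-level feature extraction and label encoding.

Each analysis epoch is summarised by a fixed-length vector (default 14
components, matching the classifier's input width):

* EEG band powers: delta, theta, alpha, beta, gamma (Welch PSD integrals,
  averaged across channels) -- 5 components;
* EEG Hjorth parameters: activity, mobility, complexity (channel-averaged)
  -- 3 components;
* GSR time-domain moments: mean, sd, skewness, excess kurtosis -- 4;
* heart-rate mean and sd -- 2.

The delta band (1-4 Hz) is largely suppressed by the 4-45 Hz EEG filter but is
still computed (near zero) so the layout covers all five canonical bands.

Labels come from 1-9 valence/arousal self-ratings via a deterministic
thresholded map onto {Exhausted=0, Negative=1, Active=2}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import SignalWindow

#: Canonical EEG band edges in Hz (half-open [low, high) in intent; the PSD
#: integral includes both edge bins).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

CLASS_NAMES: tuple[str, str, str] = ("Exhausted", "Negative", "Active")

FEATURE_NAMES: tuple[str, ...] = (
    "eeg_delta_power",
    "eeg_theta_power",
    "eeg_alpha_power",
    "eeg_beta_power",
    "eeg_gamma_power",
    "eeg_hjorth_activity",
    "eeg_hjorth_mobility",
    "eeg_hjorth_complexity",
    "gsr_mean",
    "gsr_sd",
    "gsr_skewness",
    "gsr_kurtosis",
    "hr_mean",
    "hr_sd",
)


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    label: Optional[int] = None
    subject_id: Optional[str] = None
    trial_id: Optional[str] = None
    session_period: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.names):
            raise ValueError("values and names must have the same length")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")
        if self.label is not None and self.label not in (0, 1, 2):
            raise ValueError("label must be in {0, 1, 2}")


@dataclass
class NormalizationRecord:
    """Per-feature statistics fitted on the training split only."""

    method: str
    center: np.ndarray  # mean (zscore) or min (minmax)
    scale: np.ndarray  # sd (zscore) or range (minmax)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def invert(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.center


@dataclass
class LabeledDataset:
    """Feature matrix with labels and per-row provenance metadata."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    meta: Optional[pd.DataFrame] = None
    class_names: tuple[str, ...] = CLASS_NAMES
    normalization: Optional[NormalizationRecord] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")
        valid = set(range(len(self.class_names)))
        if not set(np.unique(self.y)).issubset(valid):
            raise ValueError(f"labels must come from {sorted(valid)}")
        if self.meta is not None and len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must have one row per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=len(self.class_names))

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return replace(self, X=self.X[idx], y=self.y[idx], meta=meta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.y
        if self.meta is not None:
            for col in self.meta.columns:
                df[col] = self.meta[col].values
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, feature_names: Optional[Sequence[str]] = None
    ) -> "LabeledDataset":
        names = tuple(feature_names) if feature_names is not None else tuple(
            c for c in df.columns if c in FEATURE_NAMES
        ) or tuple(c for c in df.columns if c != "label" and df[c].dtype.kind in "fi")
        meta_cols = [c for c in df.columns if c not in names and c != "label"]
        meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
        return cls(
            X=df[list(names)].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            feature_names=names,
            meta=meta,
        )


def band_powers(
    w: SignalWindow | np.ndarray,
    fs: float,
    bands: Optional[dict[str, tuple[float, float]]] = None,
) -> np.ndarray:
    """Welch band powers integrated over each named band.

    Welch settings: Hann taper, segment length min(window, 256) with 50 %
    overlap -- a bias/variance balance appropriate at 128 Hz.
    """
    x = w.values if isinstance(w, SignalWindow) else np.asarray(w, dtype=float)
    bands = bands or DEFAULT_BANDS
    lowest = min(lo for lo, _ in bands.values())
    highest = max(hi for _, hi in bands.values())
    if highest > fs / 2:
        raise ValueError(f"band edge {highest} Hz exceeds the Nyquist limit {fs / 2} Hz")
    if x.size < 2 * fs / lowest:
        raise ValueError(
            f"window of {x.size} samples too short to resolve {lowest} Hz"
        )
    nperseg = min(x.size, 256)
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    out = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands.values()):
        sel = (freqs >= lo) & (freqs <= hi)
        out[i] = np.trapezoid(psd[sel], freqs[sel]) if sel.sum() > 1 else 0.0
    return np.maximum(out, 0.0)


def hjorth(w: SignalWindow | np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of one window.

    activity = var(x); mobility = sqrt(var(dx)/var(x)); complexity =
    mobility(dx)/mobility(x), with d the first difference.
    """
    x = w.values if isinstance(w, SignalWindow) else np.asarray(w, dtype=float)
    if x.size < 3:
        raise ValueError("Hjorth parameters need at least 3 samples")
    var0 = x.var()
    if var0 == 0:
        raise ValueError("Hjorth parameters are undefined for a constant window")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    var1 = d1.var()
    var2 = d2.var()
    activity = var0
    mobility = np.sqrt(var1 / var0)
    complexity = np.sqrt(var2 / var1) / mobility if var1 > 0 else 0.0
    return float(activity), float(mobility), float(complexity)


@dataclass
class MomentStats:
    mean: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float  # excess kurtosis
    degenerate: bool = False


def moment_stats(w: SignalWindow | np.ndarray) -> MomentStats:
    """Sample moments of one window; sd uses ddof=1, kurtosis is excess.

    A constant window is degenerate: skewness and kurtosis are reported as 0
    with the flag set.
    """
    x = w.values if isinstance(w, SignalWindow) else np.asarray(w, dtype=float)
    if x.size < 4:
        raise ValueError("moment statistics need at least 4 samples")
    if np.ptp(x) == 0:  # constant window; avoids catastrophic cancellation
        return MomentStats(float(x[0]), 0.0, 0.0, 0.0, 0.0, degenerate=True)
    sd = float(x.std(ddof=1))
    if sd == 0:
        return MomentStats(float(x.mean()), 0.0, 0.0, 0.0, 0.0, degenerate=True)
    return MomentStats(
        mean=float(x.mean()),
        sd=sd,
        variance=sd**2,
        skewness=float(spstats.skew(x)),
        kurtosis=float(spstats.kurtosis(x)),  # Fisher: normal -> 0
    )


def assemble_features(
    eeg_windows: Sequence[SignalWindow],
    gsr_window: Optional[SignalWindow],
    hr_window: Optional[SignalWindow],
    fs_eeg: float,
    bands: Optional[dict[str, tuple[float, float]]] = None,
    label: Optional[int] = None,
    subject_id: Optional[str] = None,
    trial_id: Optional[str] = None,
    session_period: Optional[str] = None,
) -> FeatureVector:
    """Build the 14-component multimodal vector for one aligned epoch.

    ``eeg_windows`` holds one window per EEG channel for the same epoch; band
    powers and Hjorth parameters are averaged across channels (the channel
    mean is permutation-invariant).
    """
    if not eeg_windows:
        raise ValueError("missing modality: EEG")
    if gsr_window is None:
        raise ValueError("missing modality: GSR")
    if hr_window is None:
        raise ValueError("missing modality: HR")
    bp = np.mean([band_powers(w, fs_eeg, bands) for w in eeg_windows], axis=0)
    hj = np.mean([hjorth(w) for w in eeg_windows], axis=0)
    g = moment_stats(gsr_window)
    h = moment_stats(hr_window)
    values = np.concatenate(
        [bp, hj, [g.mean, g.sd, g.skewness, g.kurtosis], [h.mean, h.sd]]
    )
    return FeatureVector(
        values=values,
        label=label,
        subject_id=subject_id,
        trial_id=trial_id,
        session_period=session_period,
    )


def normalize_features(
    train: np.ndarray,
    apply_to: Optional[np.ndarray] = None,
    method: str = "zscore",
) -> tuple[np.ndarray, Optional[np.ndarray], NormalizationRecord]:
    """Fit per-feature normalization on ``train`` and apply to both matrices.

    zscore: (x - mean) / sd (population sd).  minmax: (x - min) / range; rows
    outside the training range may land outside [0, 1] (no clipping).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train must be a matrix with at least 2 rows")
    if method == "zscore":
        center = train.mean(axis=0)
        scale = train.std(axis=0)
    elif method == "minmax":
        center = train.min(axis=0)
        scale = train.max(axis=0) - center
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(f"zero-spread feature(s) at column(s) {zero.tolist()}")
    rec = NormalizationRecord(method=method, center=center, scale=scale)
    train_n = rec.apply(train)
    applied = rec.apply(apply_to) if apply_to is not None else None
    return train_n, applied, rec


def map_ratings_to_state(
    valence: float,
    arousal: float,
    active_arousal: float = 6.0,
    active_valence: float = 5.0,
    negative_valence: float = 4.0,
) -> int:
    """Map 1-9 valence/arousal ratings onto {Exhausted=0, Negative=1, Active=2}.

    Default rule: arousal >= 6 and valence >= 5 -> Active; else valence < 4 ->
    Negative; otherwise Exhausted.
    """
    if not (1 <= valence <= 9 and 1 <= arousal <= 9):
        raise ValueError("valence and arousal must lie in [1, 9]")
    if arousal >= active_arousal and valence >= active_valence:
        return 2
    if valence < negative_valence:
        return 1
    return 0


#: Column index ranges of each modality inside the default feature layout.
MODALITY_SLICES: dict[str, slice] = {
    "EEG": slice(0, 8),
    "GSR": slice(8, 12),
    "HR": slice(12, 14),
}
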