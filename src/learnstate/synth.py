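"""Synthetic multimodal recordings with controllable class separability.

The generator emulates the three learner states through class-dependent
physiological phenotypes, scaled by a single ``effect_size`` knob (0 = all
classes identical):

* EEG: white noise filtered into the five canonical bands and remixed with
  state-dependent log-gains -- Active is beta/gamma-dominant, Exhausted is
  theta/alpha-dominant, Negative has a mildly mixed spectrum;
* GSR: slow tonic drift plus exponential-decay phasic events whose Poisson
  rate is highest for the Negative state;
* HR: a baseline beat-rate series whose mean rises with activation (Active
  highest, Exhausted lowest) plus autocorrelated variability;
* valence/arousal self-ratings drawn inside the region that the default
  rating-to-state rule assigns to the generating state.

Missing samples and amplitude artifacts are injected separately so the
cleaning stage is exercised on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .features import map_ratings_to_state
from .pipeline import extract_dataset
from .preprocess import Modality, PreprocessConfig, RawRecording

SESSION_PERIODS = ("morning", "afternoon", "night")

# State-dependent log-gain per band at effect_size 1, order
# (delta, theta, alpha, beta, gamma); rows: Exhausted, Negative, Active.
_BAND_SHIFT = np.array(
    [
        [0.0, 0.40, 0.30, -0.20, -0.10],  # Exhausted: slow-wave dominant
        [0.05, 0.10, -0.10, 0.10, 0.05],  # Negative: mixed spectrum
        [0.0, -0.20, -0.10, 0.40, 0.20],  # Active: beta/gamma dominant
    ]
)
_BASE_GAIN = np.array([0.5, 1.0, 1.0, 1.0, 0.5])

# GSR phasic event rate (events/s) offset and HR mean/sd shifts at effect 1.
_GSR_RATE = np.array([0.06, 0.14, 0.08])  # base rate per state at effect 1 blend
_HR_MEAN_SHIFT = np.array([-5.0, 2.0, 5.0])
_HR_SD_SHIFT = np.array([-0.5, 1.0, 0.5])

_BAND_EDGES = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 45.0))


@dataclass
class SynthConfig:
    n_per_class: int = 50
    duration_s: float = 12.0
    fs: float = 128.0
    n_eeg_channels: int = 4
    effect_size: float = 1.0
    missing_rate: float = 0.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1 and 0 <= self.artifact_rate < 1):
            raise ValueError("missing_rate and artifact_rate must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.duration_s * self.fs < 2:
            raise ValueError("recording must span at least one analysis window")


def _band_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """White noise filtered into the five canonical bands; rows = bands."""
    from scipy import signal as sps

    out = np.empty((len(_BAND_EDGES), n))
    for i, (lo, hi) in enumerate(_BAND_EDGES):
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        white = rng.standard_normal(n + int(2 * fs))
        filt = sps.sosfilt(sos, white)[int(2 * fs) :]  # drop the transient
        sd = filt.std()
        out[i] = filt / sd if sd > 0 else filt
    return out


def _rng_for(cfg: SynthConfig, trial_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(trial_seed, stream))
    )


def synth_recording(
    state: int,
    cfg: SynthConfig,
    trial_seed: int = 0,
    subject_id: str = "s01",
    trial_id: Optional[str] = None,
    session_period: Optional[str] = None,
) -> dict[str, RawRecording]:
    """Generate one trial's EEG, GSR and HR recordings for a given state.

    Deterministic in (state, cfg, trial_seed).  Returns a dict keyed by
    modality name.
    """
    if state not in (0, 1, 2):
        raise ValueError("state must be 0, 1 or 2")
    n = int(round(cfg.duration_s * cfg.fs))
    trial_id = trial_id or f"t{trial_seed:04d}"
    e = cfg.effect_size

    rng = _rng_for(cfg, trial_seed, stream=state)
    # Trial-to-trial physiological variability, independent of state: log-gain
    # jitter on the EEG bands and baseline jitter on GSR/HR.  It keeps any
    # single modality only partially informative, as in real recordings.
    band_jitter = rng.normal(0.0, 0.25, size=len(_BAND_EDGES))
    gains = _BASE_GAIN * np.exp(e * _BAND_SHIFT[state] + band_jitter)
    eeg = np.empty((cfg.n_eeg_channels, n))
    for ch in range(cfg.n_eeg_channels):
        bands = _band_noise(rng, n, cfg.fs)
        eeg[ch] = gains @ bands + 0.2 * rng.standard_normal(n)

    # GSR: tonic baseline + slow drift + state-rated phasic events.
    t = np.arange(n) / cfg.fs
    tonic = (
        5.0
        + rng.normal(0.0, 0.3)
        + 0.3 * np.sin(2 * np.pi * t / (cfg.duration_s * 2) + rng.uniform(0, 2 * np.pi))
    )
    rate = (0.05 + e * (_GSR_RATE[state] - 0.05)) * np.exp(rng.normal(0.0, 0.3))
    gsr = tonic + 0.05 * rng.standard_normal(n)
    n_events = rng.poisson(max(rate, 0.0) * cfg.duration_s)
    for _ in range(n_events):
        onset = rng.integers(0, n)
        amp = rng.uniform(0.3, 1.0)
        tau = rng.uniform(1.0, 3.0) * cfg.fs
        length = n - onset
        gsr[onset:] += amp * np.exp(-np.arange(length) / tau)

    # HR: baseline beat-rate series with AR(1)-like variability.
    hr_mean = 70.0 + e * _HR_MEAN_SHIFT[state] + rng.normal(0.0, 3.0)
    hr_sd = max(3.0 + e * _HR_SD_SHIFT[state], 0.5) * np.exp(rng.normal(0.0, 0.2))
    ar = np.empty(n)
    ar[0] = rng.standard_normal()
    phi = 0.995
    innov = rng.standard_normal(n) * np.sqrt(1 - phi**2)
    for i in range(1, n):
        ar[i] = phi * ar[i - 1] + innov[i]
    hr = hr_mean + hr_sd * ar

    # Ratings inside the region the default rule maps to this state.
    if state == 2:  # Active: arousal >= 6, valence >= 5
        valence, arousal = rng.uniform(5.0, 9.0), rng.uniform(6.0, 9.0)
    elif state == 1:  # Negative: valence < 4
        valence, arousal = rng.uniform(1.0, 3.9), rng.uniform(1.0, 9.0)
    else:  # Exhausted: valence >= 4, arousal < 6
        valence, arousal = rng.uniform(4.0, 8.0), rng.uniform(1.0, 5.9)
    assert map_ratings_to_state(valence, arousal) == state

    common = dict(
        subject_id=subject_id,
        trial_id=trial_id,
        sampling_rate_hz=cfg.fs,
        ratings=(valence, arousal),
        session_period=session_period,
    )
    return {
        "EEG": RawRecording(modality=Modality.EEG, samples=eeg, **common),
        "GSR": RawRecording(modality=Modality.GSR, samples=gsr[None, :], **common),
        "HR": RawRecording(modality=Modality.HR, samples=hr[None, :], **common),
    }


def inject_missing_and_artifacts(
    rec: RawRecording, cfg: SynthConfig, seed: int = 0
) -> RawRecording:
    """Return a corrupted copy: Bernoulli missing samples plus amplitude spikes.

    Spikes are +/-(8-12) channel standard deviations, so they always exceed
    the |z| > 3 outlier threshold; the original recording is untouched.
    """
    if not (cfg.missing_rate < 1 and cfg.artifact_rate < 1):
        raise ValueError("rates must be < 1")
    rng = np.random.default_rng(seed)
    samples = rec.samples.copy()
    mask = rec.missing_mask.copy()
    for ch in range(rec.n_channels):
        x = samples[ch]
        if cfg.artifact_rate > 0:
            sd = x.std()
            hit = rng.random(x.size) < cfg.artifact_rate
            signs = rng.choice([-1.0, 1.0], size=int(hit.sum()))
            mags = rng.uniform(8.0, 12.0, size=int(hit.sum()))
            x[hit] = x[hit] + signs * mags * sd
        if cfg.missing_rate > 0:
            mask[ch] |= rng.random(x.size) < cfg.missing_rate
    return replace(rec, samples=samples, missing_mask=mask)


def synth_dataset(
    cfg: SynthConfig,
    class_counts: Optional[Sequence[int]] = None,
    run_pipeline: bool = True,
    preprocess_cfg: Optional[PreprocessConfig] = None,
):
    """Generate a full labeled corpus of recordings (optionally featurized).

    ``class_counts`` overrides the balanced default (n_per_class each).
    Session periods are attached round-robin per trial.  Returns
    ``(recordings, dataset)`` where ``recordings`` is a list of per-trial
    modality dicts and ``dataset`` is the LabeledDataset produced by the
    preprocessing + feature pipeline (None when ``run_pipeline=False``).
    """
    counts = list(class_counts) if class_counts is not None else [cfg.n_per_class] * 3
    if len(counts) != 3:
        raise ValueError("class_counts must have 3 entries")
    recordings = []
    trial_seed = 0
    for state, k in enumerate(counts):
        for _ in range(k):
            period = SESSION_PERIODS[trial_seed % 3]
            trio = synth_recording(
                state,
                cfg,
                trial_seed=trial_seed,
                subject_id=f"s{trial_seed % 8:02d}",
                trial_id=f"t{trial_seed:04d}",
                session_period=period,
            )
            if cfg.missing_rate > 0 or cfg.artifact_rate > 0:
                trio = {
                    k_: inject_missing_and_artifacts(r, cfg, seed=trial_seed * 7 + i)
                    for i, (k_, r) in enumerate(trio.items())
                }
            recordings.append(trio)
            trial_seed += 1
    ds = extract_dataset(recordings, preprocess_cfg) if run_pipeline else None
    return recordings, ds
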