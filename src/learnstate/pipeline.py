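"""End-to-end glue: raw recordings -> cleaned windows -> labeled feature table.

Each trial contributes one feature vector per EEG epoch.  Because the slower
modalities use longer windows (8 s vs 4 s by default), every EEG epoch is
paired with the GSR and HR windows that overlap it most in time.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    LabeledDataset,
    assemble_features,
    map_ratings_to_state,
)
from .preprocess import PreprocessConfig, RawRecording, SignalWindow, preprocess_recording


def _best_overlap(
    start: int, length: int, fs: float, candidates: list[SignalWindow], cand_fs: float
) -> SignalWindow:
    """The candidate window with maximal time overlap with [start, start+length)/fs."""
    t0, t1 = start / fs, (start + length) / fs
    best, best_ov = None, -1.0
    for w in candidates:
        c0 = w.start_sample / cand_fs
        c1 = (w.start_sample + len(w)) / cand_fs
        ov = min(t1, c1) - max(t0, c0)
        if ov > best_ov:
            best, best_ov = w, ov
    return best


def extract_trial(
    trio: dict[str, RawRecording],
    cfg: Optional[PreprocessConfig] = None,
) -> list:
    """Preprocess one trial's modality dict and assemble per-epoch features."""
    for mod in ("EEG", "GSR", "HR"):
        if mod not in trio:
            raise ValueError(f"missing modality: {mod}")
    cfg = cfg or PreprocessConfig()
    eeg, gsr, hr = trio["EEG"], trio["GSR"], trio["HR"]
    eeg_wins = preprocess_recording(eeg, cfg)  # one list per channel
    gsr_wins = preprocess_recording(gsr, cfg)[0]
    hr_wins = preprocess_recording(hr, cfg)[0]
    label = (
        map_ratings_to_state(*eeg.ratings) if eeg.ratings is not None else None
    )
    vectors = []
    n_epochs = len(eeg_wins[0])
    for ep in range(n_epochs):
        epoch_channels = [eeg_wins[ch][ep] for ch in range(len(eeg_wins))]
        ref = epoch_channels[0]
        gw = _best_overlap(
            ref.start_sample, len(ref), eeg.sampling_rate_hz, gsr_wins, gsr.sampling_rate_hz
        )
        hw = _best_overlap(
            ref.start_sample, len(ref), eeg.sampling_rate_hz, hr_wins, hr.sampling_rate_hz
        )
        vectors.append(
            assemble_features(
                epoch_channels,
                gw,
                hw,
                fs_eeg=eeg.sampling_rate_hz,
                label=label,
                subject_id=eeg.subject_id,
                trial_id=eeg.trial_id,
                session_period=eeg.session_period,
            )
        )
    return vectors


def extract_dataset(
    trials: Sequence[dict[str, RawRecording]],
    cfg: Optional[PreprocessConfig] = None,
) -> LabeledDataset:
    """Run the full pipeline over many trials and stack into a LabeledDataset."""
    rows, labels, meta = [], [], []
    for trio in trials:
        for fv in extract_trial(trio, cfg):
            rows.append(fv.values)
            labels.append(fv.label if fv.label is not None else -1)
            meta.append(
                {
                    "subject_id": fv.subject_id,
                    "trial_id": fv.trial_id,
                    "session_period": fv.session_period,
                    "synthetic": False,
                }
            )
    if not rows:
        raise ValueError("no trials produced any feature vectors")
    y = np.asarray(labels)
    if (y < 0).any():
        raise ValueError("some trials lack ratings; cannot assign labels")
    return LabeledDataset(
        X=np.vstack(rows),
        y=y,
        feature_names=FEATURE_NAMES,
        meta=pd.DataFrame(meta),
    )
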