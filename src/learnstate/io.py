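"""Plain-text I/O for recordings, feature tables and reports.

Recordings travel as long-format CSV (subject, trial, modality, channel,
t_index, value, missing, plus per-trial rating/period columns); feature
tables as wide CSV with a feature-name header and label/metadata columns,
round-trippable at full double precision.

A reader for DEAP-style preprocessed archives is feature-flagged: calling it
without the licensed archive present raises a clear error instead of
attempting any download.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, LabeledDataset
from .preprocess import Modality, RawRecording

_REC_COLUMNS = [
    "subject_id",
    "trial_id",
    "modality",
    "channel",
    "t_index",
    "value",
    "missing",
    "sampling_rate_hz",
    "valence",
    "arousal",
    "session_period",
]


def recordings_to_frame(recordings: Iterable[RawRecording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        v, a = rec.ratings if rec.ratings is not None else (np.nan, np.nan)
        for ch in range(rec.n_channels):
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "trial_id": rec.trial_id,
                        "modality": rec.modality.value,
                        "channel": ch,
                        "t_index": np.arange(rec.n_samples),
                        "value": rec.samples[ch],
                        "missing": rec.missing_mask[ch],
                        "sampling_rate_hz": rec.sampling_rate_hz,
                        "valence": v,
                        "arousal": a,
                        "session_period": rec.session_period,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[_REC_COLUMNS]


def write_recordings(recordings: Iterable[RawRecording], path: str) -> None:
    recordings_to_frame(recordings).to_csv(path, index=False)


def read_recordings(path: str) -> list[RawRecording]:
    """Rebuild RawRecording objects from the long-format CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (subj, trial, mod), g in df.groupby(
        ["subject_id", "trial_id", "modality"], sort=False
    ):
        channels = sorted(g["channel"].unique())
        samples, masks = [], []
        for ch in channels:
            gc = g[g["channel"] == ch].sort_values("t_index")
            samples.append(gc["value"].to_numpy())
            masks.append(gc["missing"].to_numpy(dtype=bool))
        first = g.iloc[0]
        ratings = None
        if np.isfinite(first["valence"]) and np.isfinite(first["arousal"]):
            ratings = (float(first["valence"]), float(first["arousal"]))
        period = first["session_period"]
        out.append(
            RawRecording(
                subject_id=str(subj),
                trial_id=str(trial),
                modality=Modality(mod),
                sampling_rate_hz=float(first["sampling_rate_hz"]),
                samples=np.vstack(samples),
                missing_mask=np.vstack(masks),
                ratings=ratings,
                session_period=None if pd.isna(period) else str(period),
            )
        )
    return out


def write_features(ds: LabeledDataset, path: str) -> None:
    """Wide CSV: feature columns, label, then metadata columns."""
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_features(path: str) -> LabeledDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    names = tuple(c for c in df.columns if c in FEATURE_NAMES)
    if not names:
        names = None
    return LabeledDataset.from_frame(df, feature_names=names)


def save_mlp(results, path: str) -> None:
    """Archive a fitted model: sizes, weights, biases, dropout, normalization."""
    mlp = results.mlp
    arrays = {
        "layer_sizes": np.asarray(mlp.layer_sizes),
        "keep_prob": np.asarray(mlp.keep_prob),
        "norm_center": results.normalization.center,
        "norm_scale": results.normalization.scale,
        "loss_history": np.asarray(results.loss_history),
    }
    for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def load_deap_archive(path: Optional[str] = None):
    """Feature-flagged reader for the externally licensed DEAP archive.

    The archive (per-participant trial x channel x sample arrays at 128 Hz
    with 1-9 ratings) is an optional, licensed download; this package never
    fetches it.  Raises FileNotFoundError when absent so downstream code can
    fall back to synthetic data.
    """
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(
            "DEAP archive not available; generate synthetic recordings with "
            "learnstate.synth instead"
        )
    raise NotImplementedError(
        "DEAP ingestion requires the licensed archive layout; convert it to the "
        "long-format recordings CSV and use read_recordings()"
    )
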