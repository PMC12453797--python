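"""Classification metrics, stratified cross-validation, model comparison and
group-wise breakdowns.

Precision, recall and F1 follow the usual one-vs-rest definitions

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall),

with macro averages taken as unweighted class means.  A class with an empty
denominator is scored 0 and flagged rather than dropped.

Cross-validation is stratified; when per-row trial metadata is available the
split is additionally grouped by trial so that windows cut from one recording
never straddle the train/validation boundary.  Feature normalization (and,
when enabled, GAN augmentation) is fitted on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .augment import GanConfig, balance_dataset, train_gan
from .features import LabeledDataset, normalize_features
from .mlp import TrainConfig, init_mlp, predict, train_mlp


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class EvalReport:
    confusion: np.ndarray
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined_precision: list[int] = field(default_factory=list)
    undefined_recall: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def prf_metrics(cm: np.ndarray) -> EvalReport:
    """Per-class and macro precision/recall/F1 plus accuracy from a confusion matrix."""
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    undef_p = [int(i) for i in np.flatnonzero(tp + fp == 0)]
    undef_r = [int(i) for i in np.flatnonzero(tp + fn == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return EvalReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(tp.sum() / cm.sum()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        undefined_precision=undef_p,
        undefined_recall=undef_r,
    )


@dataclass
class PipelineSpec:
    """Hyperparameters of the classifier pipeline evaluated by kfold_cv."""

    hidden: int = 78
    n_hidden_layers: int = 2
    dropout_rate: float = 0.14
    batch_size: int = 95
    learning_rate: float = 0.05
    max_iter: int = 150
    stop_threshold: float = 1e-6
    normalize: str = "zscore"
    augment: bool = False
    gan_config: Optional[GanConfig] = None
    feature_subset: Optional[slice] = None  # e.g. a single-modality column range


@dataclass
class CvAggregate:
    mean: float
    sd: float
    ci95: tuple[float, float]


@dataclass
class CvResult:
    fold_table: pd.DataFrame  # one row per (repeat, fold)
    aggregate: dict[str, CvAggregate]
    confusion_total: np.ndarray
    reports: list[EvalReport]

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.fold_table["accuracy"].to_numpy()


def _aggregate(values: np.ndarray) -> CvAggregate:
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if values.size > 1 and sd > 0:
        half = float(spstats.t.ppf(0.975, values.size - 1) * sd / np.sqrt(values.size))
    else:
        half = 0.0
    return CvAggregate(mean=m, sd=sd, ci95=(m - half, m + half))


def _fit_and_score(
    ds: LabeledDataset, tr: np.ndarray, va: np.ndarray, spec: PipelineSpec, seed: int
) -> EvalReport:
    train = ds.subset(tr)
    if spec.augment:
        counts = train.class_counts()
        if counts.min() < counts.max():
            gans = {
                c: train_gan(train.X[train.y == c], spec.gan_config or GanConfig(seed=seed))
                for c in range(len(counts))
                if counts[c] < counts.max()
            }
            train = balance_dataset(train, gans, seed=seed)
    Xtr, Xva = train.X, ds.X[va]
    if spec.feature_subset is not None:
        Xtr, Xva = Xtr[:, spec.feature_subset], Xva[:, spec.feature_subset]
    Xtr, Xva, _ = normalize_features(Xtr, Xva, method=spec.normalize)
    sizes = (
        Xtr.shape[1],
        *([spec.hidden] * spec.n_hidden_layers),
        len(ds.class_names),
    )
    model = init_mlp(sizes, seed=seed, keep_prob=1.0 - spec.dropout_rate)
    cfg = TrainConfig(
        learning_rate=spec.learning_rate,
        max_iter=spec.max_iter,
        stop_threshold=spec.stop_threshold,
        batch_size=spec.batch_size,
        seed=seed,
    )
    model, _ = train_mlp(model, Xtr, train.y, cfg)
    cm = confusion(ds.y[va], predict(model, Xva), n_classes=len(ds.class_names))
    return prf_metrics(cm)


def kfold_cv(
    spec: PipelineSpec,
    ds: LabeledDataset,
    k: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    group_by: Optional[str] = "trial_id",
) -> CvResult:
    """Stratified (and, when possible, trial-grouped) k-fold cross-validation.

    Returns per-fold metrics, the elementwise-summed confusion matrix, and a
    mean/sd/95 % t-interval aggregate per metric.  Deterministic under seed.
    """
    counts = ds.class_counts()
    if counts.min() < k:
        small = int(np.argmin(counts))
        raise ValueError(f"class {small} has only {counts.min()} members; needs >= {k}")
    groups = None
    if group_by and ds.meta is not None and group_by in ds.meta.columns:
        groups = ds.meta[group_by].to_numpy()
    rows, reports = [], []
    cm_total = np.zeros((len(ds.class_names), len(ds.class_names)), dtype=int)
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        if groups is not None:
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(ds.X, ds.y, groups=groups)
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(ds.X, ds.y)
        for fold, (tr, va) in enumerate(splits):
            rpt = _fit_and_score(ds, tr, va, spec, seed=rep_seed + fold)
            reports.append(rpt)
            cm_total += rpt.confusion
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": rpt.accuracy,
                    "macro_precision": rpt.macro_precision,
                    "macro_recall": rpt.macro_recall,
                    "macro_f1": rpt.macro_f1,
                    "n_val": int(rpt.confusion.sum()),
                }
            )
    table = pd.DataFrame(rows)
    agg = {
        m: _aggregate(table[m].to_numpy())
        for m in ("accuracy", "macro_precision", "macro_recall", "macro_f1")
    }
    return CvResult(fold_table=table, aggregate=agg, confusion_total=cm_total, reports=reports)


def compare_models(
    folds_a: np.ndarray | pd.Series, folds_b: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Paired two-sided t-test over matched fold accuracies.

    Returns (mean difference a-b, p-value).  Zero variance of the paired
    differences is degenerate and scored p = 1 by convention.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if a.size != b.size:
        raise ValueError("fold tables must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 folds for a paired test")
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]):
        return mean_diff, 1.0
    t = spstats.ttest_rel(a, b)
    return mean_diff, float(t.pvalue)


def group_breakdown(
    meta: pd.DataFrame, y_true: np.ndarray, y_pred: np.ndarray, key: str = "session_period"
) -> pd.DataFrame:
    """Accuracy and support per metadata group (empty groups omitted)."""
    if key not in meta.columns:
        raise ValueError(f"unknown metadata key {key!r}")
    df = pd.DataFrame(
        {"group": meta[key].values, "correct": np.asarray(y_true) == np.asarray(y_pred)}
    )
    out = (
        df.groupby("group", dropna=True)["correct"]
        .agg(accuracy="mean", support="size")
        .reset_index()
    )
    out["support"] = out["support"].astype(int)
    return out
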