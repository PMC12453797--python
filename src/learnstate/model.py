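"""Model/Results interface over the classifier stack.

``MlpClassifier`` wraps the from-scratch MLP behind a fit/Results API in the
style of statistical modelling packages: the model object holds the data and
architecture, ``fit()`` returns a results object carrying the trained weights,
loss history, diagnostics and a ``summary()`` table.  ``PsoMlpClassifier``
first runs particle-swarm hyperparameter search (cross-validated error as the
objective) and then fits the winning configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import LabeledDataset, normalize_features
from .mlp import MLPModel, TrainConfig, init_mlp, predict, predict_proba, train_mlp
from .pso import DEFAULT_BOUNDS, SwarmConfig, SwarmResult, decode_position, fitness, pso_optimize


class MlpClassifier:
    """Three-state learner-state classifier built on the from-scratch MLP.

    Parameters
    ----------
    X, y : array-like
        Feature matrix (n x d) and integer labels in {0, 1, 2}.
    hidden : int
        Width of each hidden layer (default 78, the swarm-optimized value).
    n_hidden_layers : int
        Number of hidden layers (default 2).
    dropout_rate : float
        Input-layer dropout rate (default 0.14); keep-probability is 1 - rate.
    """

    def __init__(
        self,
        X,
        y,
        feature_names: Optional[Sequence[str]] = None,
        meta: Optional[pd.DataFrame] = None,
        hidden: int = 78,
        n_hidden_layers: int = 2,
        dropout_rate: float = 0.14,
        normalize: str = "zscore",
    ):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=int)
        self.feature_names = (
            tuple(feature_names)
            if feature_names is not None
            else tuple(f"x{i}" for i in range(self.X.shape[1]))
        )
        self.meta = meta
        self.hidden = hidden
        self.n_hidden_layers = n_hidden_layers
        self.dropout_rate = dropout_rate
        self.normalize = normalize
        self.n_classes = 3

    @classmethod
    def from_dataset(cls, ds: LabeledDataset, **kwargs) -> "MlpClassifier":
        return cls(ds.X, ds.y, feature_names=ds.feature_names, meta=ds.meta, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "MlpClassifier":
        ds = LabeledDataset.from_frame(df.rename(columns={label_col: "label"}))
        return cls.from_dataset(ds, **kwargs)

    def _dataset(self) -> LabeledDataset:
        return LabeledDataset(
            X=self.X, y=self.y, feature_names=self.feature_names, meta=self.meta
        )

    def fit(
        self,
        learning_rate: float = 0.05,
        max_iter: int = 200,
        batch_size: int = 95,
        stop_threshold: float = 1e-6,
        seed: int = 0,
    ) -> "MlpResults":
        """Train on all rows and return a results object."""
        Xn, _, norm = normalize_features(self.X, method=self.normalize)
        sizes = (
            self.X.shape[1],
            *([self.hidden] * self.n_hidden_layers),
            self.n_classes,
        )
        model = init_mlp(sizes, seed=seed, keep_prob=1.0 - self.dropout_rate)
        cfg = TrainConfig(
            learning_rate=learning_rate,
            max_iter=max_iter,
            stop_threshold=stop_threshold,
            batch_size=batch_size,
            seed=seed,
        )
        model, history = train_mlp(model, Xn, self.y, cfg)
        return MlpResults(self, model, norm, history, cfg)

    def cross_validate(self, k: int = 5, n_repeats: int = 1, seed: int = 0, **spec_kw):
        spec = ev.PipelineSpec(
            hidden=self.hidden,
            n_hidden_layers=self.n_hidden_layers,
            dropout_rate=self.dropout_rate,
            normalize=self.normalize,
            **spec_kw,
        )
        return ev.kfold_cv(spec, self._dataset(), k=k, n_repeats=n_repeats, seed=seed)


@dataclass
class MlpResults:
    """Trained-model results: weights, loss history, in-sample diagnostics."""

    model: MlpClassifier
    mlp: MLPModel
    normalization: object
    loss_history: list[float]
    train_config: TrainConfig
    swarm: Optional[SwarmResult] = None
    best_hyperparams: Optional[dict] = None

    def _prep(self, X) -> np.ndarray:
        return self.normalization.apply(np.atleast_2d(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        return predict(self.mlp, self._prep(X))

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self.mlp, self._prep(X))

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y, dtype=int)).mean())

    def eval_report(self, X=None, y=None) -> ev.EvalReport:
        X = self.model.X if X is None else X
        y = self.model.y if y is None else y
        cm = ev.confusion(np.asarray(y, dtype=int), self.predict(X))
        return ev.prf_metrics(cm)

    def summary(self) -> str:
        rpt = self.eval_report()
        lines = [
            "Learner-State MLP Results",
            "=" * 58,
            f"{'Observations:':<28}{self.model.X.shape[0]}",
            f"{'Features:':<28}{self.model.X.shape[1]}",
            f"{'Architecture:':<28}{'-'.join(map(str, self.mlp.layer_sizes))}",
            f"{'Input dropout rate:':<28}{self.model.dropout_rate:.3f}",
            f"{'Batch size:':<28}{self.train_config.batch_size}",
            f"{'Learning rate:':<28}{self.train_config.learning_rate:g}",
            f"{'Iterations run:':<28}{len(self.loss_history)}",
            f"{'Final training loss:':<28}{self.loss_history[-1]:.4f}",
            "-" * 58,
            f"{'Training accuracy:':<28}{rpt.accuracy:.4f}",
            f"{'Macro precision:':<28}{rpt.macro_precision:.4f}",
            f"{'Macro recall:':<28}{rpt.macro_recall:.4f}",
            f"{'Macro F1:':<28}{rpt.macro_f1:.4f}",
        ]
        if self.best_hyperparams:
            lines.insert(
                2,
                f"{'PSO-selected params:':<28}"
                f"hidden={self.best_hyperparams['hidden']}, "
                f"dropout={self.best_hyperparams['dropout_rate']:.3f}, "
                f"batch={self.best_hyperparams['batch_size']}",
            )
        lines.append("=" * 58)
        return "\n".join(lines)


class PsoMlpClassifier(MlpClassifier):
    """MLP classifier whose hyperparameters are chosen by particle swarm search.

    ``fit()`` minimizes 1 - inner-CV accuracy over (hidden width, dropout
    rate, batch size) inside ``bounds`` and then trains the decoded optimum on
    the full data.
    """

    def __init__(self, X, y, bounds=DEFAULT_BOUNDS, **kwargs):
        super().__init__(X, y, **kwargs)
        self.bounds = bounds

    def fit(
        self,
        swarm: Optional[SwarmConfig] = None,
        inner_folds: int = 3,
        learning_rate: float = 0.05,
        max_iter: int = 150,
        stop_threshold: float = 1e-6,
        seed: int = 0,
    ) -> MlpResults:
        swarm = swarm or SwarmConfig(bounds=self.bounds, seed=seed)
        ds = self._dataset()
        base = TrainConfig(
            learning_rate=learning_rate,
            max_iter=max_iter,
            stop_threshold=stop_threshold,
            seed=seed,
        )

        def objective(position: np.ndarray) -> float:
            return fitness(
                position,
                ds,
                inner_folds=inner_folds,
                seed=seed,
                n_hidden_layers=self.n_hidden_layers,
                train_cfg=base,
                bounds=swarm.bounds,
            )

        result = pso_optimize(swarm, objective)
        hidden, dropout, batch = decode_position(result.best_position, swarm.bounds)
        self.hidden = hidden
        self.dropout_rate = dropout
        res = super().fit(
            learning_rate=learning_rate,
            max_iter=max_iter,
            batch_size=batch,
            stop_threshold=stop_threshold,
            seed=seed,
        )
        res.swarm = result
        res.best_hyperparams = {
            "hidden": hidden,
            "dropout_rate": dropout,
            "batch_size": batch,
        }
        return res
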