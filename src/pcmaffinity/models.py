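"""Regression models and the 10-fold cross-validation driver.

Three algorithms with fixed hyperparameters:

* RF  -- random forest, 500 trees, unlimited depth, min_samples_split 2,
  min_samples_leaf 1, no leaf-node cap;
* SVM -- epsilon-SVR with radial-basis kernel, cost 1000, gamma 1e-4
  (a gamma that small only makes sense for an RBF kernel);
* ANN -- one hidden layer of 2 units, L2 weight decay 0.1, linear output,
  at most 1000 iterations (fit with L-BFGS, the closest quasi-Newton
  analogue of the classical nnet optimiser).

Cross-validation re-fits the [-1, 1] scaling and the imputation medians on
each training partition before applying them to the held-out fold; a
``fit_on_all`` switch reproduces the simpler variant that scales on the
full table first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from pcmaffinity.evalreport import MetricsBundle, metrics
from pcmaffinity.featureset import (
    FeatureTable,
    ScalingParams,
    apply_scaling,
    fit_scaling,
    split_tenfold,
)

logger = logging.getLogger(__name__)

DEFAULT_HYPERPARAMETERS = {
    "RF": {
        "n_estimators": 500,
        "max_depth": None,
        "min_samples_split": 2,
        "min_samples_leaf": 1,
        "max_leaf_nodes": None,
    },
    "SVM": {"C": 1000.0, "gamma": 0.0001, "kernel": "rbf"},
    "ANN": {"hidden_units": 2, "decay": 0.1, "max_iter": 1000},
}

MIN_ROWS = {"RF": 10, "SVM": 2, "ANN": 10}


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; use RF, SVM or ANN")
        unknown = set(self.hyperparameters) - set(DEFAULT_HYPERPARAMETERS[self.algorithm])
        if unknown:
            raise ValueError(
                f"unknown {self.algorithm} hyperparameters {sorted(unknown)}; "
                f"valid: {sorted(DEFAULT_HYPERPARAMETERS[self.algorithm])}"
            )

    def resolved(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}


def _build_estimator(config: ModelConfig):
    hp = config.resolved()
    if config.algorithm == "RF":
        return RandomForestRegressor(random_state=config.seed, n_jobs=1, **hp)
    if config.algorithm == "SVM":
        return SVR(C=hp["C"], gamma=hp["gamma"], kernel=hp["kernel"])
    return MLPRegressor(
        hidden_layer_sizes=(hp["hidden_units"],),
        alpha=hp["decay"],
        max_iter=hp["max_iter"],
        solver="lbfgs",
        random_state=config.seed,
    )


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    scaling: ScalingParams
    manifest: list[str]
    config: ModelConfig

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def train(config: ModelConfig, table: FeatureTable,
          scaling: ScalingParams | None = None) -> TrainedModel:
    """Fit one model on the whole table (scaling fitted on it unless given)."""
    if table.n_rows < MIN_ROWS[config.algorithm]:
        raise ValueError(
            f"{config.algorithm} needs >= {MIN_ROWS[config.algorithm]} rows, "
            f"got {table.n_rows}"
        )
    if not np.isfinite(table.y.to_numpy()).all():
        raise ValueError("response contains non-finite values")
    params = scaling if scaling is not None else fit_scaling(table.X)
    Xs = apply_scaling(table.X, params)
    est = _build_estimator(config)
    est.fit(Xs.to_numpy(float), table.y.to_numpy(float))
    logger.info("trained %s with %s on %d rows x %d columns",
                config.algorithm, config.resolved(), *Xs.shape)
    return TrainedModel(
        algorithm=config.algorithm, estimator=est, scaling=params,
        manifest=[str(c) for c in table.X.columns], config=config,
    )


def predict(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted log2 affinity for raw (unscaled) descriptor rows."""
    got = [str(c) for c in rows.columns]
    if set(got) != set(model.manifest):
        missing = sorted(set(model.manifest) - set(got))
        extra = sorted(set(got) - set(model.manifest))
        raise KeyError(f"column manifest mismatch: missing {missing[:5]}, extra {extra[:5]}")
    Xs = apply_scaling(rows[model.manifest], model.scaling)
    return np.asarray(model.estimator.predict(Xs.to_numpy(float)), dtype=float)


@dataclass
class CVReport:
    algorithm: str
    fold_metrics: pd.DataFrame      # rows: fold x partition, metric columns
    folds: list[np.ndarray]
    seed: int

    def aggregate(self, how: str = "mean") -> pd.DataFrame:
        """One row per partition with metric means over folds (the default),
        or metrics pooled over all held-out predictions via ``how="pooled"``
        (pooling is only defined for per-sample metrics, handled upstream)."""
        if how != "mean":
            raise ValueError("pooled aggregation is produced by crossvalidate directly")
        return self.fold_metrics.groupby("partition").mean(numeric_only=True)

    def to_csv(self, path) -> None:
        self.fold_metrics.to_csv(path, index=False)


def crossvalidate(
    config: ModelConfig,
    table: FeatureTable,
    seed: int = 0,
    n_folds: int = 10,
    fit_on_all: bool = False,
) -> CVReport:
    """10-fold cross-validation with per-fold preprocessing.

    Rows are partitioned at random into near-equal folds; each fold in turn
    is the test set while the rest train the model.  All five metrics are
    reported per fold on both partitions.
    """
    n = table.n_rows
    folds = split_tenfold(n, seed=seed, n_folds=n_folds)
    rows = []
    shared = fit_scaling(table.X) if fit_on_all else None
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        params = shared if shared is not None else fit_scaling(table.X.iloc[train_idx])
        try:
            Xtr = apply_scaling(table.X.iloc[train_idx], params)
            Xte = apply_scaling(table.X.iloc[test_idx], params)
            ytr = table.y.iloc[train_idx].to_numpy(float)
            yte = table.y.iloc[test_idx].to_numpy(float)
            est = _build_estimator(config)
            est.fit(Xtr.to_numpy(float), ytr)
        except Exception as exc:
            raise RuntimeError(f"fold {k}: training failed: {exc}") from exc
        for partition, X_, y_ in (("train", Xtr, ytr), ("test", Xte, yte)):
            m = metrics(y_, est.predict(X_.to_numpy(float)))
            rows.append({"fold": k, "partition": partition, **m.as_dict()})
    report = CVReport(
        algorithm=config.algorithm,
        fold_metrics=pd.DataFrame(rows),
        folds=folds,
        seed=seed,
    )
    agg = report.aggregate()
    logger.info("%s %d-fold CV: train R2 %.4f, test R2 %.4f",
                config.algorithm, n_folds, agg.loc["train", "R2"], agg.loc["test", "R2"])
    return report


def aggregate_metrics(report: CVReport) -> dict[str, MetricsBundle]:
    """Mean-over-folds metrics per partition as MetricsBundle objects."""
    agg = report.aggregate()
    out = {}
    for part in ("train", "test"):
        row = agg.loc[part]
        out[part] = MetricsBundle(
            sse=row["SSE"], mse=row["MSE"], rmse=row["RMSE"], mae=row["MAE"],
            r2=row["R2"], n=int(row["n"]),
        )
    return out
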