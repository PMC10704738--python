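"""ROS inference regressors and their evaluation.

Two regressors predict log10 ROS from the selected descriptors:

* a feed-forward neural network — three relu hidden layers (128/64/32) plus a
  linear output, trained with Adam on mean squared error for 100 epochs;
* a random-forest baseline (100 trees, unlimited depth).

Evaluation reports RMSE on the log scale plus precision / recall / F-measure
obtained by binarising both the targets and the predictions at the modulator
threshold (positive = predicted/actual modulator).  The harmonic-mean
identity F = 2PR/(P+R) is an invariant of :class:`EvalMetrics`.

Two protocols are provided.  The default mirrors the motivating study:
oversample first, then split 90/10 — the test split then contains synthetic
points interpolated from training-set modulators, which inflates the metrics
(documented leakage).  :func:`holdout_generalization` instead removes a
stratified 10% of each class *before* oversampling and scores the untouched
holdout, measuring genuine generalisation; the gap between the two is itself
a property the test suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .augment import SmoteConfig, smote_resample
from .data_io import (
    DEFAULT_THRESHOLD,
    CompoundLibrary,
    FeatureScaler,
    apply_scaler,
    fit_scaler,
)


@dataclass
class DnnConfig:
    """Neural-network hyperparameters (relu/adam/mse, 100 epochs)."""

    hidden_sizes: tuple[int, ...] = (128, 64, 32)
    activation: str = "relu"
    optimizer: str = "adam"
    epochs: int = 100
    loss: str = "mse"
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class RfConfig:
    """Random-forest baseline hyperparameters (100 trees, no depth cap)."""

    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class RosModel:
    """A fitted log-ROS regressor plus everything needed to apply it.

    ``predict`` takes *unscaled* descriptors in the model's feature order and
    applies the stored scaler itself, so a screening table only has to carry
    the right columns.
    """

    kind: str  # "dnn" | "rf"
    config: DnnConfig | RfConfig
    selected_features: list[str]
    scaler: FeatureScaler
    estimator: object
    threshold: float = DEFAULT_THRESHOLD


@dataclass
class EvalMetrics:
    """RMSE plus threshold-binarised classification metrics.

    Ratios with a zero denominator are reported as None (flagged null),
    never silently as 0.
    """

    rmse: float
    precision: float | None
    recall: float | None
    f_measure: float | None
    n: int
    counts: dict = field(default_factory=dict)  # tp/fp/fn/tn

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "n": self.n,
            **{k: int(v) for k, v in self.counts.items()},
        }


def split_train_test(
    X: np.ndarray, y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive partition with round(N*fraction) test rows.

    Returns ``(X_train, X_test, y_train, y_test)``; the underlying index
    arrays are available via :func:`split_indices`.
    """
    tr, te = split_indices(len(np.asarray(y)), test_fraction, seed)
    X = np.asarray(X)
    y = np.asarray(y)
    return X[tr], X[te], y[tr], y[te]


def split_indices(n: int, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Permutation split into (train, test) index arrays."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("split would leave an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: DnnConfig | RfConfig,
    selected_features: Sequence[str] | None = None,
    scaler: FeatureScaler | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> RosModel:
    """Fit a regressor on (already scaled) training data.

    ``scaler`` is the transformer that produced ``X_train``; it is stored on
    the model so that :func:`predict` can accept raw descriptors.  When no
    scaler is given an identity-equivalent one is fit on X_train itself.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if selected_features is None:
        selected_features = [f"f{i}" for i in range(X_train.shape[1])]
    if scaler is None:
        scaler = FeatureScaler(
            means=np.zeros(X_train.shape[1]), stddevs=np.ones(X_train.shape[1])
        )

    if isinstance(config, DnnConfig):
        est = MLPRegressor(
            hidden_layer_sizes=tuple(config.hidden_sizes),
            activation=config.activation,
            solver=config.optimizer,
            max_iter=config.epochs,
            batch_size=config.batch_size,
            learning_rate_init=config.learning_rate,
            random_state=config.seed,
            early_stopping=False,
            n_iter_no_change=config.epochs,  # always run the full epoch budget
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X_train, y_train)
        losses = np.asarray(est.loss_curve_)
        if not np.all(np.isfinite(losses)):
            epoch = int(np.flatnonzero(~np.isfinite(losses))[0]) + 1
            raise ArithmeticError(f"non-finite training loss at epoch {epoch}")
        kind = "dnn"
    elif isinstance(config, RfConfig):
        est = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
        est.fit(X_train, y_train)
        kind = "rf"
    else:
        raise TypeError(f"unsupported config type {type(config).__name__}")

    return RosModel(
        kind=kind,
        config=config,
        selected_features=list(selected_features),
        scaler=scaler,
        estimator=est,
        threshold=threshold,
    )


def predict(
    model: RosModel,
    X: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Predicted log10 ROS for unscaled descriptors.

    If ``feature_names`` is given it must match the model's feature list
    exactly (order included); a mismatch raises with the missing/extra names.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None:
        if list(feature_names) != model.selected_features:
            missing = set(model.selected_features) - set(feature_names)
            extra = set(feature_names) - set(model.selected_features)
            raise ValueError(
                f"feature mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
    if X.ndim != 2 or X.shape[1] != len(model.selected_features):
        raise ValueError(
            f"expected {len(model.selected_features)} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    pred = model.estimator.predict(apply_scaler(model.scaler, X))
    return np.asarray(pred, dtype=float)


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> EvalMetrics:
    """RMSE plus precision/recall/F from binarising both vectors at threshold.

    RMSE = sqrt(mean((y_i - yhat_i)^2)); precision = TP/(TP+FP),
    recall = TP/(TP+FN), F = 2PR/(P+R).  Zero denominators yield None.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    pos_t = y_true >= threshold
    pos_p = y_pred >= threshold
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f = 0.0
    else:
        f = None
    return EvalMetrics(
        rmse=rmse,
        precision=precision,
        recall=recall,
        f_measure=f,
        n=len(y_true),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


@dataclass
class HoldoutResult:
    metrics: EvalMetrics
    holdout_indices: np.ndarray
    smote_parent_indices: np.ndarray
    model: RosModel


def holdout_generalization(
    library: CompoundLibrary,
    model_config: DnnConfig | RfConfig,
    smote_config: SmoteConfig | None = None,
    selected_features: Sequence[str] | None = None,
    holdout_fraction: float = 0.10,
    seed: int = 0,
) -> HoldoutResult:
    """Score generalisation to compounds unseen by SMOTE and training.

    A stratified ``holdout_fraction`` of each class is removed *before*
    oversampling; SMOTE and training use only the remainder; metrics are
    computed on the untouched holdout.  The returned result carries the
    holdout indices and the SMOTE parent indices (disjoint by construction,
    asserted in tests via provenance).
    """
    lib = library.training_view()
    if selected_features is not None:
        lib = lib.select_features(selected_features)
    labels = lib.labels
    y = lib.log_ros
    rng = np.random.default_rng(seed)

    holdout: list[int] = []
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        n_hold = int(round(len(idx) * holdout_fraction))
        if n_hold < 1 or n_hold >= len(idx):
            raise ValueError(
                f"holdout of {holdout_fraction:.0%} would empty class {cls}"
            )
        holdout.extend(rng.choice(idx, size=n_hold, replace=False))
    holdout_idx = np.sort(np.array(holdout))
    rest_idx = np.setdiff1d(np.arange(len(lib)), holdout_idx)

    scaler = fit_scaler(lib.X[rest_idx])
    Xs = apply_scaler(scaler, lib.X[rest_idx])
    X_aug, _, y_aug, prov = smote_resample(
        Xs, labels[rest_idx], smote_config or SmoteConfig(), y=y[rest_idx]
    )
    model = train(
        X_aug,
        y_aug,
        model_config,
        selected_features=lib.feature_names,
        scaler=scaler,
        threshold=lib.threshold,
    )
    pred = predict(model, lib.X[holdout_idx])
    metrics = evaluate(y[holdout_idx], pred, lib.threshold)
    parents = (
        rest_idx[prov["parent_index"].to_numpy()] if len(prov) else np.array([], int)
    )
    return HoldoutResult(
        metrics=metrics,
        holdout_indices=holdout_idx,
        smote_parent_indices=np.unique(parents),
        model=model,
    )
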