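"""SMOTE oversampling of the modulator minority class, from scratch.

Synthetic Minority Over-sampling Technique (Chawla et al. 2002): each
synthetic sample is a point on the segment between a minority compound x and
one of its k nearest minority neighbours z, x + u*(z - x) with u ~ U(0,1).
The minority class is oversampled until its count equals the majority count
(sampling strategy "minority data").  Distances are Euclidean in the caller's
(z-scored) feature space; neighbour ties break toward the lower row index and
the neighbour set excludes the point itself.

When a regression target y (log10 ROS) is supplied it is interpolated with
the same u as the descriptors, so synthetic rows carry a consistent target
for downstream regression training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SmoteConfig:
    """Oversampling hyperparameters (defaults: 5 neighbours, seed 42)."""

    k_neighbors: int = 5
    seed: int = 42
    strategy: str = "minority_to_majority"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.strategy != "minority_to_majority":
            raise ValueError(f"unknown sampling strategy {self.strategy!r}")


def amplification_factor(minority_n: int, majority_n: int) -> float:
    """Ratio majority/minority: the per-original synthetic-sample quota.

    Fractional quotas are resolved at sampling time by randomised assignment
    of the remainder across minority points.
    """
    if minority_n < 1:
        raise ValueError("minority_n must be >= 1")
    return majority_n / minority_n


def _minority_knn(Xm: np.ndarray, k: int) -> np.ndarray:
    """Indices (into the minority set) of each point's k nearest neighbours.

    Brute-force Euclidean distances; self excluded; ties broken by lower row
    index (stable argsort on the distance matrix).
    """
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def smote_resample(
    X: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig | None = None,
    y: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame] | tuple[
    np.ndarray, np.ndarray, np.ndarray, pd.DataFrame
]:
    """Oversample the minority class to match the majority count.

    Parameters
    ----------
    X
        N x F feature matrix (z-scored; distances are Euclidean here).
    labels
        Boolean vector; True marks the minority (modulator) class if it is
        the smaller one — the minority class is detected from counts.
    config
        :class:`SmoteConfig`; defaults to k=5, seed 42.
    y
        Optional regression target, interpolated alongside X.

    Returns
    -------
    (X_aug, labels_aug[, y_aug], provenance)
        Originals first (input order), synthetic minority rows appended.
        ``provenance`` has one row per synthetic sample with columns
        ``synthetic_id, parent_index, neighbor_index, u`` (indices into the
        original matrix).

    Raises
    ------
    ValueError
        If only one class is present, or the minority class has fewer than
        ``k_neighbors + 1`` members.
    """
    config = config or SmoteConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for SMOTE")

    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    minority_value = n_pos <= n_neg
    min_idx = np.flatnonzero(labels == minority_value)
    n_min, n_maj = len(min_idx), len(labels) - len(min_idx)
    if n_min < config.k_neighbors + 1:
        raise ValueError(
            f"minority class of {n_min} is too small for k={config.k_neighbors}"
        )

    n_needed = n_maj - n_min
    empty_prov = pd.DataFrame(
        columns=["synthetic_id", "parent_index", "neighbor_index", "u"]
    )
    if n_needed == 0:
        if y is not None:
            return X.copy(), labels.copy(), np.asarray(y, float).copy(), empty_prov
        return X.copy(), labels.copy(), empty_prov

    rng = np.random.default_rng(config.seed)
    Xm = X[min_idx]
    neigh = _minority_knn(Xm, config.k_neighbors)

    # per-original quota: floor for everyone, remainder assigned at random
    base, rem = divmod(n_needed, n_min)
    counts = np.full(n_min, base, dtype=int)
    if rem:
        counts[rng.choice(n_min, size=rem, replace=False)] += 1
    parents_local = np.repeat(np.arange(n_min), counts)
    neighbor_pick = rng.integers(0, config.k_neighbors, size=n_needed)
    neighbors_local = neigh[parents_local, neighbor_pick]
    u = rng.uniform(0.0, 1.0, size=n_needed)

    Xp, Xz = Xm[parents_local], Xm[neighbors_local]
    X_new = Xp + u[:, None] * (Xz - Xp)
    X_aug = np.vstack([X, X_new])
    labels_aug = np.concatenate([labels, np.full(n_needed, minority_value, bool)])

    provenance = pd.DataFrame(
        {
            "synthetic_id": np.arange(len(labels), len(labels) + n_needed),
            "parent_index": min_idx[parents_local],
            "neighbor_index": min_idx[neighbors_local],
            "u": u,
        }
    )
    if y is not None:
        y = np.asarray(y, dtype=float)
        y_new = y[min_idx[parents_local]] + u * (
            y[min_idx[neighbors_local]] - y[min_idx[parents_local]]
        )
        return X_aug, labels_aug, np.concatenate([y, y_new]), provenance
    return X_aug, labels_aug, provenance


def write_provenance(provenance: pd.DataFrame, path) -> None:
    """CSV sidecar: one row per synthetic sample (parent, neighbour, u)."""
    provenance.to_csv(path, index=False)
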