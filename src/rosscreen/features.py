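"""Descriptor selection: random-forest importance ranking and elbow cut.

A random-forest regressor (100 trees, unlimited depth by default) is fit on
the un-augmented library with log10 ROS as the target; impurity-decrease
importances rank the descriptors.  The working subset is either a configured
top-k (the motivating screen used k=47) or, as a fallback, the knee of the
sorted-importance curve located by the maximum-perpendicular-distance
(chord/"kneedle") rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class FeatureRanking:
    """Descriptors sorted by descending importance."""

    ordered_names: list[str]
    importances: np.ndarray  # matching order, non-negative, sums to 1
    selected_k: int
    rf_seed: int

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if np.any(np.diff(self.importances) > 1e-12):
            raise ValueError("importances must be non-increasing in rank order")
        if abs(self.importances.sum() - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
    method: str = "impurity",
) -> FeatureRanking:
    """Rank descriptors by random-forest importance on the regression target.

    Parameters
    ----------
    X, y
        Descriptor matrix and log10 ROS target (un-augmented library).
    n_trees, seed
        Forest size and random state (defaults 100 trees, seed 0).
    method
        ``"impurity"`` (default) for mean-decrease-in-impurity importances;
        ``"permutation"`` for permutation importances (robustness checks).

    Ties in importance break toward the lower original column index, so the
    ranking is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples to rank features")
    if np.ptp(y) == 0:
        raise ValueError("constant target: no split gain definable")
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_depth=None, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    if method == "impurity":
        imp = rf.feature_importances_.astype(float)
    elif method == "permutation":
        res = permutation_importance(rf, X, y, n_repeats=5, random_state=seed)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    order = np.argsort(-imp, kind="stable")
    ordered = imp[order]
    ranking = FeatureRanking(
        ordered_names=[feature_names[i] for i in order],
        importances=ordered,
        selected_k=max(1, elbow_index(ordered)),
        rf_seed=seed,
    )
    return ranking


def elbow_index(sorted_importances: np.ndarray) -> int:
    """Knee of a descending curve: max perpendicular distance to the chord.

    The chord runs from the first to the last point of the curve
    (rank, importance); the returned index is the point farthest from it —
    on a sharp knee this is the first point *after* the drop, so the index
    doubles as the count of features preceding the knee.
    """
    v = np.asarray(sorted_importances, dtype=float)
    n = len(v)
    if n < 3:
        return n - 1
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], v[0]])
    p1 = np.array([x[-1], v[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return n - 1
    rel = np.stack([x - p0[0], v - p0[1]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def select_top_k(ranking: FeatureRanking, k: int | None = None) -> list[str]:
    """First k names of the ranking; elbow rule when k is None.

    The output is always a prefix of ``ranking.ordered_names``.
    """
    F = len(ranking.ordered_names)
    if k is None:
        k = max(1, elbow_index(ranking.importances))
    if not (1 <= k <= F):
        raise ValueError(f"k={k} out of range [1, {F}]")
    return ranking.ordered_names[:k]


def write_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    """CSV with columns ``rank,feature,importance`` (rank starts at 1)."""
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.ordered_names) + 1),
            "feature": ranking.ordered_names,
            "importance": ranking.importances,
        }
    ).to_csv(path, index=False)


def write_selection(names: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(names) + "\n")


def read_selection(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
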