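"""The screening funnel: threshold first pass and compartment-based selection.

Stage 1 streams an arbitrarily large descriptor table in chunks (5,000 rows
by default), predicts log10 ROS with a fitted model, and keeps compounds
whose prediction is at or above the modulator threshold.  The candidate set
is invariant to chunk size and input order.

Stage 2 works on the 2-D GTM map: the [-1,1]^2 square is partitioned into an
8x8 grid of 64 compartments (row-major ids from the bottom-left corner, the
top/right boundary closed).  Within every compartment that contains at least
one reference modulator, candidates are ranked by (a) ascending distance to
their nearest reference and (b) descending predicted log ROS; the combined
score is the rank sum, and the best ``per_compartment_quota`` candidates are
selected.  Rank sums keep the rule scale-free — no unit mixing between map
distance and log luminescence.  Compounds on an exclusion list (e.g. known
deleterious chemistry) are never selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_io import iter_descriptor_chunks
from .ros_model import RosModel, predict

logger = logging.getLogger(__name__)


@dataclass
class CompartmentGrid:
    """Partition of [-1,1]^2 into n_rows x n_cols half-open cells.

    Cell id = row * n_cols + col, rows counted from the bottom; the top and
    right boundaries (coordinate exactly 1.0) belong to the last row/column,
    so the cells are disjoint and exhaustive.
    """

    n_rows: int = 8
    n_cols: int = 8

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class SelectionConfig:
    per_compartment_quota: int = 10
    exclude_ids: frozenset = field(default_factory=frozenset)
    global_cap: int | None = None  # optional overall ceiling after ranking

    def __post_init__(self) -> None:
        if self.per_compartment_quota < 0:
            raise ValueError("quota must be >= 0")
        self.exclude_ids = frozenset(self.exclude_ids)


@dataclass
class ScreeningFunnel:
    """Per-stage candidate accounting: input -> 1st screen -> 2nd screen."""

    n_input: int = 0
    stage1_ids: list = field(default_factory=list)
    stage1_predictions: dict = field(default_factory=dict)
    stage2_ids: list | None = None
    threshold: float | None = None
    configs: dict = field(default_factory=dict)

    @property
    def n_first_pass(self) -> int:
        return len(self.stage1_ids)

    @property
    def n_second_pass(self) -> int | None:
        return None if self.stage2_ids is None else len(self.stage2_ids)


def screen_first_pass(
    source: str | Path | Iterable[tuple[np.ndarray, np.ndarray]],
    model: RosModel,
    threshold: float | None = None,
    chunk_size: int = 5000,
) -> ScreeningFunnel:
    """Stream a descriptor table and keep compounds predicted at/above threshold.

    ``source`` is either a CSV/TSV path (columns: id + the model's selected
    features, extra columns ignored) or an iterable of ``(ids, X)`` chunks.
    Memory stays bounded by one chunk; results are identical for any
    chunk_size.
    """
    t = model.threshold if threshold is None else threshold
    if isinstance(source, (str, Path)):
        chunks = iter_descriptor_chunks(source, model.selected_features, chunk_size)
    else:
        chunks = source

    funnel = ScreeningFunnel(threshold=t, configs={"chunk_size": chunk_size})
    for ids, X in chunks:
        pred = predict(model, X)
        keep = pred >= t
        funnel.n_input += len(ids)
        for cid, p in zip(ids[keep], pred[keep]):
            funnel.stage1_ids.append(cid)
            funnel.stage1_predictions[cid] = float(p)
        logger.info(
            "screened %d compounds, %d candidates so far",
            funnel.n_input,
            funnel.n_first_pass,
        )
    return funnel


def assign_compartment(
    coords: np.ndarray, grid: CompartmentGrid | None = None
) -> np.ndarray:
    """Map 2-D coordinates in [-1,1]^2 to compartment ids.

    Half-open cells [lo, hi) with the closing boundary at +1; out-of-bounds
    coordinates raise.
    """
    grid = grid or CompartmentGrid()
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    if c.shape[1] != 2:
        raise ValueError("coords must be N x 2")
    if np.any(c < -1.0) or np.any(c > 1.0):
        bad = np.argwhere((c < -1.0) | (c > 1.0))[0][0]
        raise ValueError(f"coordinate out of [-1,1]^2 at row {bad}")
    col = np.minimum(((c[:, 0] + 1.0) / 2.0 * grid.n_cols).astype(int), grid.n_cols - 1)
    row = np.minimum(((c[:, 1] + 1.0) / 2.0 * grid.n_rows).astype(int), grid.n_rows - 1)
    return row * grid.n_cols + col


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    """1-based min-ranks of ascending values: rank = 1 + #(strictly smaller)."""
    v = np.asarray(values, dtype=float)
    return 1 + (v[:, None] > v[None, :]).sum(axis=1)


def secondary_select(
    candidate_ids: Sequence,
    candidate_coords: np.ndarray,
    candidate_predictions: np.ndarray,
    reference_coords: np.ndarray,
    grid: CompartmentGrid | None = None,
    config: SelectionConfig | None = None,
) -> tuple[list, pd.DataFrame]:
    """Rank-sum selection of candidates near reference modulators, per compartment.

    Within each compartment containing >= 1 reference projection, every
    candidate gets rank_d (ascending distance to its nearest reference,
    anywhere on the map) and rank_p (descending prediction); combined score
    rank_d + rank_p, ties broken by higher prediction then lexicographic id.
    The top ``per_compartment_quota`` per compartment are selected.
    Compartments without a reference contribute nothing.

    Returns the selected ids (deterministic order: compartment, then rank)
    and a detail table with per-candidate ranks.
    """
    grid = grid or CompartmentGrid()
    config = config or SelectionConfig()
    ids = np.asarray(candidate_ids, dtype=object)
    coords = np.asarray(candidate_coords, dtype=float)
    preds = np.asarray(candidate_predictions, dtype=float)
    refs = np.atleast_2d(np.asarray(reference_coords, dtype=float))
    if len(refs) == 0:
        raise ValueError("empty reference set")

    detail_columns = [
        "compound_id", "compartment", "distance_to_nearest_reference",
        "prediction", "rank_d", "rank_p", "score", "selected",
    ]
    cand_cells = assign_compartment(coords, grid)
    ref_cells = set(assign_compartment(refs, grid).tolist())
    nearest_ref = cdist(coords, refs).min(axis=1) if len(ids) else np.empty(0)

    selected: list = []
    rows = []
    for cell in sorted(ref_cells):
        in_cell = np.flatnonzero(cand_cells == cell)
        if len(in_cell) == 0:
            continue
        rank_d = _competition_ranks(nearest_ref[in_cell])
        rank_p = _competition_ranks(-preds[in_cell])
        score = rank_d + rank_p
        eligible = [
            i for i in range(len(in_cell))
            if str(ids[in_cell[i]]) not in config.exclude_ids
        ]
        order = sorted(
            eligible,
            key=lambda i: (score[i], -preds[in_cell[i]], str(ids[in_cell[i]])),
        )
        take = order[: config.per_compartment_quota]
        for r, i in enumerate(order):
            rows.append(
                {
                    "compound_id": ids[in_cell[i]],
                    "compartment": cell,
                    "distance_to_nearest_reference": nearest_ref[in_cell[i]],
                    "prediction": preds[in_cell[i]],
                    "rank_d": int(rank_d[i]),
                    "rank_p": int(rank_p[i]),
                    "score": int(score[i]),
                    "selected": i in take,
                }
            )
        selected.extend(ids[in_cell[i]] for i in take)

    if config.global_cap is not None and len(selected) > config.global_cap:
        detail = pd.DataFrame(rows, columns=detail_columns)
        sel_rows = detail[detail["selected"]].sort_values(
            ["score", "prediction", "compound_id"],
            ascending=[True, False, True],
            kind="stable",
        )
        keep = set(sel_rows["compound_id"].head(config.global_cap))
        selected = [cid for cid in selected if cid in keep]
        detail["selected"] = detail["compound_id"].isin(keep) & detail["selected"]
        return selected, detail

    return selected, pd.DataFrame(rows, columns=detail_columns)


def apply_secondary(
    funnel: ScreeningFunnel,
    candidate_coords: np.ndarray,
    reference_coords: np.ndarray,
    grid: CompartmentGrid | None = None,
    config: SelectionConfig | None = None,
) -> ScreeningFunnel:
    """Run stage 2 on a stage-1 funnel (coords aligned with stage1_ids order)."""
    preds = np.array([funnel.stage1_predictions[c] for c in funnel.stage1_ids])
    selected, _ = secondary_select(
        funnel.stage1_ids, candidate_coords, preds, reference_coords, grid, config
    )
    funnel.stage2_ids = list(selected)
    funnel.configs["selection"] = {
        "quota": (config or SelectionConfig()).per_compartment_quota
    }
    return funnel


def funnel_report(funnel: ScreeningFunnel) -> dict:
    """Structured per-stage counts (JSON-ready); stage 2 absent, not zero,
    when it has not run."""
    report = {
        "total_screened": funnel.n_input,
        "first_pass_candidates": funnel.n_first_pass,
        "threshold": funnel.threshold,
        "configs": funnel.configs,
    }
    if funnel.stage2_ids is not None:
        report["second_pass_candidates"] = funnel.n_second_pass
    return report


def funnel_text(funnel: ScreeningFunnel) -> str:
    lines = [
        "Screening funnel",
        f"  total screened:        {funnel.n_input:>10,}",
        f"  1st-pass candidates:   {funnel.n_first_pass:>10,}",
    ]
    if funnel.stage2_ids is not None:
        lines.append(f"  2nd-pass candidates:   {funnel.n_second_pass:>10,}")
    else:
        lines.append("  2nd-pass candidates:   (not run)")
    return "\n".join(lines)


def write_funnel(funnel: ScreeningFunnel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(funnel_report(funnel), indent=2))
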