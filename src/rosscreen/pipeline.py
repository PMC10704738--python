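"""End-to-end orchestration: label -> select features -> SMOTE -> train ->
evaluate -> screen -> GTM -> secondary select.

One master seed fans out deterministically to the per-stage seeds (fixed
offsets), so a run is reproducible from ``(config, seed)`` alone.  The
paper-faithful profile keeps the published stage seeds (SMOTE 42, forests 0).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from . import __version__
from .augment import SmoteConfig, smote_resample
from .data_io import (
    DEFAULT_THRESHOLD,
    CompoundLibrary,
    apply_scaler,
    fit_scaler,
    read_library,
)
from .features import rank_features, select_top_k
from .gtm import GtmConfig, gtm_fit, gtm_project
from .ros_model import (
    DnnConfig,
    EvalMetrics,
    RfConfig,
    RosModel,
    evaluate,
    predict,
    split_indices,
    train,
)
from .screening import (
    CompartmentGrid,
    ScreeningFunnel,
    SelectionConfig,
    apply_secondary,
    funnel_text,
    screen_first_pass,
    write_funnel,
)

logger = logging.getLogger(__name__)

# fixed offsets from the master seed, one per randomised stage
_SEED_OFFSETS = {"smote": 1, "split": 2, "dnn": 3, "rf": 4, "gtm": 5}


@dataclass
class PipelineConfig:
    """Everything a full screening run needs; round-trips through YAML."""

    threshold: float = DEFAULT_THRESHOLD
    n_selected_features: int | None = 47
    test_fraction: float = 0.10
    split_first: bool = False  # True = pre-SMOTE holdout protocol
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    dnn: DnnConfig = field(default_factory=DnnConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    gtm: GtmConfig = field(default_factory=GtmConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    grid: CompartmentGrid = field(default_factory=CompartmentGrid)
    backend: str = "dnn"  # "dnn" | "rf"
    evaluate_rf_baseline: bool = True
    run_gtm: bool = True
    chunk_size: int = 5000
    seed: int = 0
    paper_faithful_seeds: bool = True  # keep SMOTE 42 / forest 0 as published

    def stage_seed(self, stage: str) -> int:
        if self.paper_faithful_seeds and stage == "smote":
            return self.smote.seed
        if self.paper_faithful_seeds and stage in ("rf",):
            return self.rf.seed
        return (self.seed * 1000 + _SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineResult:
    funnel: ScreeningFunnel
    model: RosModel
    metrics_train: EvalMetrics
    metrics_test: EvalMetrics
    rf_metrics_test: EvalMetrics | None
    selected_features: list[str]
    manifest: dict


def _config_dict(cfg) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (frozenset, set)):
            return sorted(enc(v) for v in obj)
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    for key, cls in [
        ("smote", SmoteConfig),
        ("dnn", DnnConfig),
        ("rf", RfConfig),
        ("gtm", GtmConfig),
        ("selection", SelectionConfig),
        ("grid", CompartmentGrid),
    ]:
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = dict(kwargs[key])
            if key == "dnn" and "hidden_sizes" in sub:
                sub["hidden_sizes"] = tuple(sub["hidden_sizes"])
            if key == "gtm":
                for gk in ("map_size", "rbf_grid"):
                    if gk in sub:
                        sub[gk] = tuple(sub[gk])
            if key == "selection" and "exclude_ids" in sub:
                sub["exclude_ids"] = frozenset(sub["exclude_ids"])
            kwargs[key] = cls(**sub)
    return PipelineConfig(**kwargs)


def train_ros_model(
    library: CompoundLibrary, config: PipelineConfig
) -> tuple[RosModel, EvalMetrics, EvalMetrics, EvalMetrics | None, list[str]]:
    """Phase 1: feature selection, oversampling, training and evaluation.

    Default protocol (as published): oversample the full labelled library,
    then split 90/10 and evaluate on the test split.  Note the test split
    then contains synthetic interpolants of training modulators; use
    ``split_first=True`` (or :func:`rosscreen.ros_model.holdout_generalization`)
    for a leakage-free estimate.
    """
    lib = library.training_view()
    y = lib.log_ros
    labels = lib.labels

    ranking = rank_features(
        lib.X, y, lib.feature_names,
        n_trees=config.rf.n_trees, seed=config.stage_seed("rf"),
    )
    k = config.n_selected_features
    if k is not None:
        k = min(k, len(ranking.ordered_names))  # small tables keep everything
    selected = select_top_k(ranking, k)
    sub = lib.select_features(selected)
    scaler = fit_scaler(sub.X)
    Xs = apply_scaler(scaler, sub.X)

    smote_cfg = SmoteConfig(
        k_neighbors=config.smote.k_neighbors,
        seed=config.stage_seed("smote"),
        strategy=config.smote.strategy,
    )
    X_aug, labels_aug, y_aug, _ = smote_resample(Xs, labels, smote_cfg, y=y)
    logger.info(
        "SMOTE: %d -> %d rows (%d per class)",
        len(labels), len(labels_aug), int(labels_aug.sum()),
    )

    tr, te = split_indices(len(y_aug), config.test_fraction, config.stage_seed("split"))
    model_cfg = (
        dataclasses.replace(config.dnn, seed=config.stage_seed("dnn"))
        if config.backend == "dnn"
        else dataclasses.replace(config.rf, seed=config.stage_seed("rf"))
    )
    model = train(
        X_aug[tr], y_aug[tr], model_cfg,
        selected_features=selected, scaler=scaler, threshold=config.threshold,
    )
    # the model scales internally; undo the pipeline scaling before predict
    inv_tr = scaler.inverse_transform(X_aug[tr])
    inv_te = scaler.inverse_transform(X_aug[te])
    m_train = evaluate(y_aug[tr], predict(model, inv_tr), config.threshold)
    m_test = evaluate(y_aug[te], predict(model, inv_te), config.threshold)

    rf_test = None
    if config.evaluate_rf_baseline and config.backend == "dnn":
        rf_model = train(
            X_aug[tr], y_aug[tr],
            dataclasses.replace(config.rf, seed=config.stage_seed("rf")),
            selected_features=selected, scaler=scaler, threshold=config.threshold,
        )
        rf_test = evaluate(y_aug[te], predict(rf_model, inv_te), config.threshold)

    return model, m_train, m_test, rf_test, selected


def run_pipeline(
    config: PipelineConfig,
    library: CompoundLibrary | None = None,
    library_path: str | Path | None = None,
    screen_source=None,
    reference_library: CompoundLibrary | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full screen and (optionally) persist all artifacts.

    ``screen_source`` is a descriptor-table path or a re-iterable sequence of
    ``(ids, X)`` chunks (a list, not a one-shot generator: stage 2 re-reads
    the candidate rows); when omitted, stage 1 screens the training library
    itself (useful for demos).  ``reference_library`` provides the known-modulator
    projections for stage 2; defaults to the training library's modulators.
    """
    stage = "setup"
    try:
        if library is None:
            if library_path is None:
                raise ValueError("either library or library_path is required")
            library = read_library(library_path, threshold=config.threshold)

        stage = "train"
        model, m_train, m_test, rf_test, selected = train_ros_model(library, config)

        stage = "screen"
        if screen_source is None:
            lib_sel = library.select_features(selected)
            screen_source = [(lib_sel.ids, lib_sel.X)]
        funnel = screen_first_pass(
            screen_source, model, config.threshold, config.chunk_size
        )

        if config.run_gtm and funnel.n_first_pass > 0:
            stage = "gtm"
            refs = reference_library or library
            refs = refs.training_view()
            ref_mask = refs.labels
            ref_X = refs.select_features(selected).X[ref_mask]
            cand_X = _collect_candidates(screen_source, selected, funnel)
            gtm_scaler = fit_scaler(np.vstack([cand_X, ref_X]))
            joint = apply_scaler(gtm_scaler, np.vstack([cand_X, ref_X]))
            gtm_cfg = dataclasses.replace(config.gtm, seed=config.stage_seed("gtm"))
            gtm_model = gtm_fit(joint, gtm_cfg)
            coords = gtm_project(gtm_model, joint)
            cand_coords = coords[: len(cand_X)]
            ref_coords = coords[len(cand_X):]
            stage = "select"
            funnel = apply_secondary(
                funnel, cand_coords, ref_coords, config.grid, config.selection
            )

        manifest = {
            "rosscreen_version": __version__,
            "seed": config.seed,
            "config": _config_dict(config),
            "config_hash": hashlib.sha256(
                json.dumps(_config_dict(config), sort_keys=True).encode()
            ).hexdigest()[:16],
            "n_input": funnel.n_input,
            "n_first_pass": funnel.n_first_pass,
            "n_second_pass": funnel.n_second_pass,
            "selected_features": selected,
            "metrics_test": m_test.as_dict(),
        }
        result = PipelineResult(
            funnel=funnel,
            model=model,
            metrics_train=m_train,
            metrics_test=m_test,
            rf_metrics_test=rf_test,
            selected_features=selected,
            manifest=manifest,
        )
        if out_dir is not None:
            stage = "write"
            _persist(result, Path(out_dir))
        logger.info("%s", funnel_text(funnel))
        return result
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise


def _collect_candidates(screen_source, selected, funnel) -> np.ndarray:
    """Re-assemble the stage-1 candidates' descriptor rows in stage-1 order."""
    wanted = {cid: i for i, cid in enumerate(funnel.stage1_ids)}
    rows = [None] * len(wanted)
    if isinstance(screen_source, (str, Path)):
        from .data_io import iter_descriptor_chunks

        chunks = iter_descriptor_chunks(screen_source, selected)
    else:
        chunks = screen_source
    for ids, X in chunks:
        for j, cid in enumerate(ids):
            if cid in wanted:
                rows[wanted[cid]] = X[j]
    return np.asarray(rows, dtype=float)


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(result.model, out_dir / "ros_model.joblib")
    (out_dir / "selected_features.txt").write_text(
        "\n".join(result.selected_features) + "\n"
    )
    metrics = {
        "train": result.metrics_train.as_dict(),
        "test": result.metrics_test.as_dict(),
    }
    if result.rf_metrics_test is not None:
        metrics["rf_baseline_test"] = result.rf_metrics_test.as_dict()
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    write_funnel(result.funnel, out_dir / "funnel.json")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    if result.funnel.stage2_ids is not None:
        (out_dir / "stage2_ids.txt").write_text(
            "\n".join(str(c) for c in result.funnel.stage2_ids) + "\n"
        )
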