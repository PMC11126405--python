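"""High-level pipeline steps: region derivation, training, prediction.

These functions wire the modules into the full workflow — class-average
segmentation, breakpoint-union regions, cohort-scaled region features, LOF
cleaning, cascade (or flat 10-class) training with a stratified held-out
split, and prediction on external cohorts — and are what the CLI wraps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import (
    ALL_CLASSES,
    DEFAULT_BINARY_CONFIG,
    DEFAULT_MULTICLASS_CONFIG,
    BoostConfig,
    HyperparameterSpace,
    ModelBundle,
    ModelError,
    PAIRS,
    merge_labels,
    pair_key,
    predict,
    predict_flat10,
    random_search,
    stratified_folds,
    train_cascade,
    train_flat10,
)
from .core import Cohort
from .metrics import metrics_report
from .outliers import filter_intraclass_outliers
from .pcf import segment_profile
from .regions import (
    FeatureMatrix,
    RegionSet,
    build_regions,
    class_average_profile,
    cohort_features,
    scale_features,
)

logger = logging.getLogger("cnclust")

#: Pipeline defaults for class-average profile segmentation. Class averages
#: suppress probe noise by 1/sqrt(class size), so the penalty is small on the
#: per-probe SSE scale; see docs for the calibration argument.
DEFAULT_GAMMA = 0.5
DEFAULT_KMIN = 3


@dataclass
class TrainConfig:
    """Everything tunable in one training run (all seeds explicit)."""

    gamma: float = DEFAULT_GAMMA
    kmin: int = DEFAULT_KMIN
    lof_k: int = 20
    lof_threshold: float = 1.5
    n_folds: int = 5
    n_trials: int = 0  # 0 = skip random search, use the default configs
    holdout_fraction: float = 0.2
    seed: int = 0
    space: HyperparameterSpace = field(default_factory=HyperparameterSpace)
    multiclass_config: BoostConfig = field(default_factory=lambda: DEFAULT_MULTICLASS_CONFIG)
    binary_config: BoostConfig = field(default_factory=lambda: DEFAULT_BINARY_CONFIG)


def derive_regions(cohort: Cohort, gamma: float = DEFAULT_GAMMA, kmin: int = DEFAULT_KMIN) -> RegionSet:
    """Class-average profiles -> per-class PCF -> breakpoint-union regions."""
    if not cohort.labels:
        raise ModelError("region derivation needs a labeled cohort")
    classes = sorted(set(cohort.labels.values()))
    segmentations = []
    for cls in classes:
        avg = class_average_profile(cohort, cls)
        seg = segment_profile(avg, gamma=gamma, kmin=kmin)
        logger.info("class %s: %d segments", cls, seg.n_segments)
        segmentations.append(seg)
    extents = cohort.chromosome_extents()
    regions = build_regions(
        segmentations,
        extents,
        provenance={"gamma": gamma, "kmin": kmin, "classes": classes},
    )
    logger.info("region set: %d regions", len(regions))
    return regions


def stratified_split(labels: dict[str, int], holdout_fraction: float, seed: int):
    """Per-class shuffled split into (train_ids, holdout_ids)."""
    rng = np.random.default_rng(seed)
    train_ids, holdout_ids = [], []
    by_class: dict[int, list[str]] = {}
    for sid in sorted(labels):
        by_class.setdefault(labels[sid], []).append(sid)
    for cls in sorted(by_class):
        ids = by_class[cls]
        perm = rng.permutation(len(ids))
        n_hold = max(1, int(round(holdout_fraction * len(ids)))) if holdout_fraction > 0 else 0
        for j, pi in enumerate(perm):
            (holdout_ids if j < n_hold else train_ids).append(ids[pi])
    return sorted(train_ids), sorted(holdout_ids)


def _select_configs(
    features: FeatureMatrix, labels: dict[str, int], config: TrainConfig
) -> tuple[BoostConfig, dict[str, BoostConfig]]:
    """Random-search the multiclass and per-pair binary configs (if enabled)."""
    if config.n_trials < 1:
        return config.multiclass_config, {pair_key(p): config.binary_config for p in PAIRS}
    x = features.values
    y10 = np.array([labels[s] for s in features.sample_ids])
    merged_levels = sorted({merge_labels(c) for c in y10})
    y6 = np.array([merged_levels.index(merge_labels(c)) for c in y10])
    folds = stratified_folds(y6, k=config.n_folds, seed=config.seed)
    best_multi, _ = random_search(
        x, y6, folds, config.space, config.n_trials, objective="logloss", seed=config.seed
    )
    binary_configs: dict[str, BoostConfig] = {}
    for pi, pair in enumerate(PAIRS):
        mask = (y10 == pair[0]) | (y10 == pair[1])
        yb = (y10[mask] == pair[1]).astype(np.int64)
        bfolds = stratified_folds(yb, k=config.n_folds, seed=config.seed + 1 + pi)
        best_bin, _ = random_search(
            x[mask], yb, bfolds, config.space, config.n_trials,
            objective="rmse", seed=config.seed + 1 + pi,
        )
        binary_configs[pair_key(pair)] = best_bin
    return best_multi, binary_configs


@dataclass
class TrainResult:
    bundle: ModelBundle
    holdout_predictions: pd.DataFrame | None
    holdout_report: dict | None
    lof_results: dict
    retained_ids: list[str]
    flat10_model: object | None = None


def train_pipeline(
    cohort: Cohort,
    regions: RegionSet | None = None,
    config: TrainConfig | None = None,
    train_flat10_too: bool = False,
) -> TrainResult:
    """Full training workflow on a labeled cohort.

    Steps: stratified 80/20 split -> regions from the training portion (unless
    given) -> cohort-scaled region features -> intra-class LOF cleaning ->
    (optional) random search -> cascade training -> held-out evaluation.
    """
    config = config or TrainConfig()
    present = sorted(set(cohort.labels.values()))
    missing = [c for c in ALL_CLASSES if c not in present]
    if missing:
        raise ModelError(f"cohort is missing IntClust class(es) {missing}")

    train_ids, holdout_ids = stratified_split(
        cohort.labels, config.holdout_fraction, seed=config.seed
    )
    train_cohort = cohort.subset(train_ids)
    if regions is None:
        regions = derive_regions(train_cohort, gamma=config.gamma, kmin=config.kmin)

    feats = cohort_features(train_cohort, regions)
    scaled, scaler = scale_features(feats)
    retained, lof_results = filter_intraclass_outliers(
        scaled, cohort.labels, k=config.lof_k, threshold=config.lof_threshold
    )
    n_removed = len(train_ids) - len(retained)
    logger.info("LOF removed %d intra-class outliers", n_removed)
    scaled_kept = FeatureMatrix(scaled.df.loc[retained], scaled=True)
    labels_kept = {s: cohort.labels[s] for s in retained}

    multi_cfg, bin_cfgs = _select_configs(scaled_kept, labels_kept, config)
    bundle = train_cascade(
        scaled_kept,
        labels_kept,
        multiclass_config=multi_cfg,
        binary_configs=bin_cfgs,
        seed=config.seed,
        regions=regions,
        scaler=scaler,
    )
    bundle.metadata.update(
        {
            "gamma": config.gamma,
            "kmin": config.kmin,
            "lof_k": config.lof_k,
            "lof_threshold": config.lof_threshold,
            "lof_removed": n_removed,
            "n_folds": config.n_folds,
            "n_trials": config.n_trials,
        }
    )

    flat10 = None
    if train_flat10_too:
        flat10 = train_flat10(scaled_kept, labels_kept, config=multi_cfg, seed=config.seed)

    holdout_pred = holdout_report = None
    if holdout_ids:
        holdout_pred, holdout_report = predict_cohort(cohort.subset(holdout_ids), bundle)
    return TrainResult(
        bundle=bundle,
        holdout_predictions=holdout_pred,
        holdout_report=holdout_report,
        lof_results=lof_results,
        retained_ids=retained,
        flat10_model=flat10,
    )


def predict_cohort(cohort: Cohort, bundle: ModelBundle) -> tuple[pd.DataFrame, dict | None]:
    """Scale a cohort with its own fit and run the cascade.

    Returns (predictions, metrics report) — the report only when the cohort
    carries labels.
    """
    feats = cohort_features(cohort, bundle.regions)
    scaled, _ = scale_features(feats)
    pred = predict(bundle, scaled)
    report = None
    if cohort.labels:
        truth = [cohort.labels[s] for s in pred.index]
        report = metrics_report(truth, pred["final_label"].tolist(), labels=list(ALL_CLASSES))
    return pred, report


def predict_cohort_flat10(cohort: Cohort, model, regions: RegionSet) -> tuple[pd.DataFrame, dict | None]:
    feats = cohort_features(cohort, regions)
    scaled, _ = scale_features(feats)
    pred = predict_flat10(model, scaled)
    report = None
    if cohort.labels:
        truth = [cohort.labels[s] for s in pred.index]
        report = metrics_report(truth, pred["final_label"].tolist(), labels=list(ALL_CLASSES))
    return pred, report
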