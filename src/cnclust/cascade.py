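"""6-class + binary-reclassification cascade over gradient-boosted trees.

Four pairs of IntClusts with near-identical copy-number profiles — (1,5),
(3,8), (4,7) and (9,10) — are merged for an initial 6-class multiclass model;
a sample landing in a merged class is then resolved by a pair-specific binary
model trained only on that pair's samples. A flat 10-class model is provided
for comparison. Hyperparameters are chosen by random search under stratified
k-fold cross-validation, minimizing mean multiclass log-loss (multiclass) or
root-mean-square error (binary) on the held-out folds.

The boosted-tree backend is XGBoost (histogram method, single thread, seeded),
which routes missing feature values natively, so NaN features are accepted
end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb

from .regions import FeatureMatrix, RegionSet, ScalingParams

#: The published merged pairs, keyed "<low>/<high>".
PAIRS: tuple[tuple[int, int], ...] = ((1, 5), (3, 8), (4, 7), (9, 10))

#: Fixed order of the 6 merged levels (model class encoding follows this).
MERGED_LEVELS: tuple[str, ...] = ("1/5", "2", "3/8", "4/7", "6", "9/10")

_MERGE_MAP: dict[int, str] = {}
for _lo, _hi in PAIRS:
    _MERGE_MAP[_lo] = f"{_lo}/{_hi}"
    _MERGE_MAP[_hi] = f"{_lo}/{_hi}"
for _singleton in (2, 6):
    _MERGE_MAP[_singleton] = str(_singleton)

ALL_CLASSES: tuple[int, ...] = tuple(range(1, 11))


class ModelError(ValueError):
    pass


def merge_labels(label: int) -> str:
    """Map an IntClust label 1..10 to its merged 6-level label."""
    try:
        return _MERGE_MAP[int(label)]
    except (KeyError, ValueError, TypeError):
        raise ModelError(f"label must be an integer in 1..10, got {label!r}") from None


def pair_key(pair: tuple[int, int]) -> str:
    return f"{pair[0]}/{pair[1]}"


# ---------------------------------------------------------------------------
# cross-validation folds and random hyperparameter search
# ---------------------------------------------------------------------------

def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Fold index per sample: per class, shuffle and deal round-robin.

    Folds are disjoint, cover every sample, and per class the fold sizes
    differ by at most one. Raises if any class has fewer than k members.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ModelError(f"need at least 2 folds, got {k}")
    folds = np.full(len(y), -1, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in sorted(pd.unique(y).tolist(), key=str):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ModelError(f"class {cls!r} has {len(idx)} < k = {k} samples")
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


@dataclass(frozen=True)
class BoostConfig:
    """One boosted-tree configuration (shared by multiclass and binary models).

    The default row/column subsampling is deliberately aggressive: features are
    cohort-wise z-scored, so their absolute location can drift slightly from
    cohort to cohort, and an ensemble that spreads its splits over many
    correlated regions tolerates that drift far better than one that pins a
    single region against a tight threshold.
    """

    max_depth: int = 4
    learning_rate: float = 0.1
    n_estimators: int = 200
    subsample: float = 0.8
    colsample_bytree: float = 0.5
    reg_lambda: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostConfig":
        return cls(**d)


DEFAULT_MULTICLASS_CONFIG = BoostConfig()
DEFAULT_BINARY_CONFIG = BoostConfig(max_depth=3)


@dataclass(frozen=True)
class HyperparameterSpace:
    """Sampling ranges for random search (learning rate is log-uniform)."""

    max_depth: tuple[int, int] = (2, 10)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    n_estimators: tuple[int, int] = (50, 500)
    subsample: tuple[float, float] = (0.5, 1.0)
    colsample_bytree: tuple[float, float] = (0.5, 1.0)
    reg_lambda: tuple[float, float] = (0.0, 5.0)

    def sample(self, rng: np.random.Generator) -> BoostConfig:
        lo, hi = self.learning_rate
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return BoostConfig(
            max_depth=int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            learning_rate=lr,
            n_estimators=int(rng.integers(self.n_estimators[0], self.n_estimators[1] + 1)),
            subsample=float(rng.uniform(*self.subsample)),
            colsample_bytree=float(rng.uniform(*self.colsample_bytree)),
            reg_lambda=float(rng.uniform(*self.reg_lambda)),
        )


@dataclass
class TrialResult:
    config: BoostConfig
    fold_objectives: list[float]
    mean_objective: float


def _make_classifier(config: BoostConfig, seed: int, n_classes: int) -> xgb.XGBClassifier:
    params = dict(
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        reg_lambda=config.reg_lambda,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )
    if n_classes == 2:
        params["objective"] = "binary:logistic"
    else:
        params.update(objective="multi:softprob", num_class=n_classes)
    model = xgb.XGBClassifier(**params)
    return _tag_classifier(model)


def _tag_classifier(model: xgb.XGBClassifier) -> xgb.XGBClassifier:
    # xgboost's save_model validates via the `_estimator_type` attribute,
    # which newer scikit-learn mixins no longer define
    model._estimator_type = "classifier"
    return model


def _logloss(y: np.ndarray, proba: np.ndarray, n_classes: int) -> float:
    eps = 1e-15
    p = np.clip(proba[np.arange(len(y)), y], eps, 1.0)
    return float(-np.mean(np.log(p)))


def _rmse(y: np.ndarray, p: np.ndarray) -> float:
    return float(np.sqrt(np.mean((p - y) ** 2)))


def random_search(
    x: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    space: HyperparameterSpace,
    n_trials: int,
    objective: str,
    seed: int,
) -> tuple[BoostConfig, list[TrialResult]]:
    """Random hyperparameter search under pre-assigned CV folds.

    ``y`` must be integer-encoded from 0; ``objective`` is "logloss"
    (softmax multiclass) or "rmse" (binary, RMSE of the predicted class-1
    probability against the 0/1 encoding). Each fold serves once as the
    validation set with the rest as training; the config with the lowest mean
    objective wins (first on ties). Deterministic given the seed.
    """
    if n_trials < 1:
        raise ModelError("n_trials must be >= 1")
    if objective not in ("logloss", "rmse"):
        raise ModelError(f"unknown objective {objective!r}")
    n_classes = int(y.max()) + 1
    rng = np.random.default_rng(seed)
    k = int(folds.max()) + 1
    trials: list[TrialResult] = []
    best: TrialResult | None = None
    for t in range(n_trials):
        config = space.sample(rng)
        fold_obj: list[float] = []
        for f in range(k):
            tr, va = folds != f, folds == f
            model = _make_classifier(config, seed=seed + t, n_classes=max(n_classes, 2))
            model.fit(x[tr], y[tr])
            if objective == "logloss":
                fold_obj.append(_logloss(y[va], model.predict_proba(x[va]), n_classes))
            else:
                fold_obj.append(_rmse(y[va], model.predict_proba(x[va])[:, 1]))
        mean_obj = float(np.mean(fold_obj))
        if not np.isfinite(mean_obj):
            warnings.warn(f"trial {t} produced a non-finite objective; discarded", stacklevel=2)
            continue
        trial = TrialResult(config, fold_obj, mean_obj)
        trials.append(trial)
        if best is None or mean_obj < best.mean_objective:
            best = trial
    if best is None:
        raise ModelError("all trials produced non-finite objectives")
    return best.config, trials


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _check_training_inputs(features: FeatureMatrix, labels: dict[str, int]) -> np.ndarray:
    y = np.array([labels.get(s, -1) for s in features.sample_ids], dtype=np.int64)
    if (y < 0).any():
        raise ModelError("every training sample must carry an IntClust label")
    present = set(y.tolist())
    missing = [c for c in ALL_CLASSES if c not in present]
    if missing:
        raise ModelError(f"training cohort is missing IntClust class(es) {missing}")
    return y


def train_flat10(
    features: FeatureMatrix,
    labels: dict[str, int],
    config: BoostConfig = DEFAULT_MULTICLASS_CONFIG,
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Single 10-class softmax model over region features (labels 1..10)."""
    y = _check_training_inputs(features, labels)
    model = _make_classifier(config, seed=seed, n_classes=10)
    model.fit(features.values, y - 1)
    return model


def predict_flat10(model: xgb.XGBClassifier, features: FeatureMatrix) -> pd.DataFrame:
    proba = model.predict_proba(features.values)
    out = pd.DataFrame(proba, index=features.sample_ids, columns=[f"ic{c}" for c in ALL_CLASSES])
    out.insert(0, "final_label", proba.argmax(axis=1) + 1)
    return out


@dataclass
class ModelBundle:
    """Everything needed to classify a new cohort.

    One 6-class model over merged labels, one binary model per merged pair
    (lower-numbered class encoded 0, higher 1), the region set defining the
    feature space, the training cohort's scaling parameters (recorded for
    provenance; new cohorts are scaled with their own fit), and metadata.
    """

    multiclass_model: xgb.XGBClassifier
    binary_models: dict[str, xgb.XGBClassifier]
    regions: RegionSet
    scaler: ScalingParams | None
    label_scheme: dict[int, str] = field(default_factory=lambda: dict(_MERGE_MAP))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {pair_key(p) for p in PAIRS}
        if set(self.binary_models) != expected:
            raise ModelError(
                f"binary models must cover exactly the merged pairs {sorted(expected)}, "
                f"got {sorted(self.binary_models)}"
            )


def train_cascade(
    features: FeatureMatrix,
    labels: dict[str, int],
    multiclass_config: BoostConfig = DEFAULT_MULTICLASS_CONFIG,
    binary_configs: dict[str, BoostConfig] | None = None,
    seed: int = 0,
    regions: RegionSet | None = None,
    scaler: ScalingParams | None = None,
) -> ModelBundle:
    """Train the 6-class model plus the four pair-specific binary models."""
    y = _check_training_inputs(features, labels)
    merged = np.array([MERGED_LEVELS.index(merge_labels(c)) for c in y])
    multi = _make_classifier(multiclass_config, seed=seed, n_classes=len(MERGED_LEVELS))
    multi.fit(features.values, merged)

    binaries: dict[str, xgb.XGBClassifier] = {}
    for pair in PAIRS:
        key = pair_key(pair)
        cfg = (binary_configs or {}).get(key, DEFAULT_BINARY_CONFIG)
        mask = (y == pair[0]) | (y == pair[1])
        if not (y == pair[0]).any() or not (y == pair[1]).any():
            raise ModelError(f"pair {key} has an empty side in the training cohort")
        yb = (y[mask] == pair[1]).astype(np.int64)  # higher-numbered class -> 1
        model = _make_classifier(cfg, seed=seed, n_classes=2)
        model.fit(features.values[mask], yb)
        binaries[key] = model

    if regions is None:
        regions = _regions_placeholder(features)
    meta = {
        "seed": seed,
        "multiclass_config": multiclass_config.to_dict(),
        "binary_configs": {
            pair_key(p): (binary_configs or {}).get(pair_key(p), DEFAULT_BINARY_CONFIG).to_dict()
            for p in PAIRS
        },
        "binary_selection_metric": "rmse",
        "binary_training_objective": "binary:logistic",
        "n_training_samples": len(features.sample_ids),
    }
    return ModelBundle(
        multiclass_model=multi,
        binary_models=binaries,
        regions=regions,
        scaler=scaler,
        metadata=meta,
    )


def _regions_placeholder(features: FeatureMatrix) -> RegionSet:
    """Reconstruct a RegionSet from "chr:start-end" feature column ids."""
    from .regions import Region

    regs = []
    for rid in features.region_ids:
        chrom, span = rid.split(":")
        lo, hi = span.split("-")
        regs.append(Region(chrom, int(lo), int(hi)))
    return RegionSet(regs, provenance={"reconstructed_from_features": True})


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(bundle: ModelBundle, features: FeatureMatrix) -> pd.DataFrame:
    """Cascade prediction with composed 10-class probabilities.

    The 6-class argmax decides the merged group; a merged pair is resolved by
    its binary model (probability >= 0.5 -> higher-numbered class). The
    composed 10-vector distributes each merged probability over its pair as
    (1 - p, p) and copies singleton probabilities; it sums to 1 by
    construction. Requires a cohort-scaled feature matrix whose columns match
    the bundle's regions.
    """
    if not features.scaled:
        raise ModelError("feature matrix must be scaled (cohort-wise z-scoring) before prediction")
    if features.region_ids != bundle.regions.region_ids:
        raise ModelError(
            f"feature dimension mismatch: {len(features.region_ids)} columns vs "
            f"{len(bundle.regions)} bundle regions"
        )
    x = features.values
    merged_probs = bundle.multiclass_model.predict_proba(x)
    binary_probs = {key: bundle.binary_models[key].predict_proba(x)[:, 1] for key in bundle.binary_models}

    n = x.shape[0]
    composed = np.zeros((n, 10))
    for li, level in enumerate(MERGED_LEVELS):
        if "/" in level:
            lo, hi = (int(v) for v in level.split("/"))
            p = binary_probs[level]
            composed[:, lo - 1] = merged_probs[:, li] * (1.0 - p)
            composed[:, hi - 1] = merged_probs[:, li] * p
        else:
            composed[:, int(level) - 1] = merged_probs[:, li]

    merged_argmax = merged_probs.argmax(axis=1)
    final = np.zeros(n, dtype=np.int64)
    used_binary_prob = np.full(n, np.nan)
    for i in range(n):
        level = MERGED_LEVELS[merged_argmax[i]]
        if "/" in level:
            lo, hi = (int(v) for v in level.split("/"))
            p = binary_probs[level][i]
            used_binary_prob[i] = p
            final[i] = hi if p >= 0.5 else lo  # exact ties go to the higher class
        else:
            final[i] = int(level)

    out = pd.DataFrame(composed, index=features.sample_ids, columns=[f"ic{c}" for c in ALL_CLASSES])
    out.insert(0, "final_label", final)
    out.insert(1, "merged_label", [MERGED_LEVELS[m] for m in merged_argmax])
    out.insert(2, "binary_prob", used_binary_prob)
    return out
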