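"""Local Outlier Factor scoring and intra-class outlier removal.

Outliers are scored independently within each class so that a sample is
flagged only when it is atypical *for its own subtype*; removal cleans the
training cohort before model fitting. LOF values near 1 indicate density
typical of a point's neighborhood, values well above 1 indicate isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .regions import FeatureMatrix


class OutlierError(ValueError):
    pass


@dataclass
class LOFResult:
    sample_ids: list[str]
    k: int
    scores: np.ndarray
    removed: np.ndarray  # boolean per sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lof": self.scores, "removed": self.removed.astype(bool)},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def lof_scores(points: np.ndarray, k: int) -> np.ndarray:
    """Classical LOF scores with k nearest neighbors (Euclidean metric).

    Requires n >= k + 1 and a complete (no-missing) matrix.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise OutlierError("points must be a 2-D array")
    if np.isnan(x).any():
        raise OutlierError("LOF requires complete data; impute missing values first")
    n = x.shape[0]
    if k < 1:
        raise OutlierError(f"k must be >= 1, got {k}")
    if n <= k:
        raise OutlierError(f"need more than k={k} points, got n={n}")
    lof = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    lof.fit(x)
    return -lof.negative_outlier_factor_


def _impute_class_median(x: np.ndarray) -> np.ndarray:
    """Column-median imputation used only inside the LOF metric space."""
    x = x.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(x, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = med[nan_c]
    return x


def filter_intraclass_outliers(
    features: FeatureMatrix,
    labels: dict[str, int],
    k: int = 20,
    threshold: float = 1.5,
) -> tuple[list[str], dict[int, LOFResult]]:
    """Remove per-class LOF outliers (score > threshold) from a training set.

    Classes with <= k + 1 members are too small for a k-neighbor density
    estimate and are skipped (all retained) with a warning. Missing feature
    values are median-imputed per class for the distance computation only.
    Returns the retained sample ids (original order) and per-class results.
    """
    unlabeled = [s for s in features.sample_ids if s not in labels]
    if unlabeled:
        raise OutlierError(f"unlabeled samples in feature matrix: {unlabeled[:5]}")
    results: dict[int, LOFResult] = {}
    removed_ids: set[str] = set()
    for class_id in sorted(set(labels[s] for s in features.sample_ids)):
        ids = [s for s in features.sample_ids if labels[s] == class_id]
        x = features.df.loc[ids].to_numpy()
        if len(ids) <= k + 1:
            warnings.warn(
                f"class {class_id} has {len(ids)} <= k+1 = {k + 1} members; LOF skipped",
                stacklevel=2,
            )
            results[class_id] = LOFResult(
                ids, k, np.ones(len(ids)), np.zeros(len(ids), dtype=bool)
            )
            continue
        scores = lof_scores(_impute_class_median(x), k)
        removed = scores > threshold
        removed_ids.update(np.asarray(ids)[removed])
        results[class_id] = LOFResult(ids, k, scores, removed)
    retained = [s for s in features.sample_ids if s not in removed_ids]
    return retained, results
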