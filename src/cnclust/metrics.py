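"""Confusion matrix and the classification metric suite.

Per-class rates are one-vs-rest: recall TP/(TP+FN), precision TP/(TP+FP),
specificity TN/(TN+FP), balanced accuracy (recall+specificity)/2, F1. Overall
summaries report micro- (pooled counts), macro- and support-weighted averages
side by side; for single-label multiclass prediction micro recall, precision
and F1 all equal accuracy (trace/total), but the variants can differ under
macro/weighted averaging, so all are labeled explicitly. The multiclass
Matthews correlation coefficient uses the K-class generalization from the
confusion-matrix marginals.

Undefined rates (0/0) are reported as NaN and excluded from macro averages
(with a count of excluded classes), never silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise MetricsError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise MetricsError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.labels, name="true")
        cols = pd.Index(self.labels, name="predicted")
        return pd.DataFrame(self.counts, index=idx, columns=cols)

    def row_percent(self) -> pd.DataFrame:
        """Row-normalized percentage view; the diagonal equals recall (in %)."""
        sup = self.supports.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / sup[:, None]
        df = self.to_frame().astype(float)
        df.loc[:, :] = pct
        return df


def confusion(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """Count confusion matrix over an explicit (or observed) label set."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise MetricsError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if labels is None:
        labels = sorted(set(t.tolist()) | set(p.tolist()), key=str)
    labels = list(labels)
    lut = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t.tolist(), p.tolist()):
        if ti not in lut or pi not in lut:
            raise MetricsError(f"label {ti!r}/{pi!r} outside the declared label set")
        counts[lut[ti], lut[pi]] += 1
    return ConfusionMatrix(counts, labels)


def _ovr_counts(cm: ConfusionMatrix):
    c = cm.counts
    tp = np.diag(c).astype(float)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp
    return tp, fp, fn, tn


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest rates per class; 0/0 cells are NaN (undefined)."""
    tp, fp, fn, tn = _ovr_counts(cm)
    recall = _safe_div(tp, tp + fn)
    precision = _safe_div(tp, tp + fp)
    specificity = _safe_div(tn, tn + fp)
    balanced = (recall + specificity) / 2.0
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    return pd.DataFrame(
        {
            "support": cm.supports,
            "recall": recall,
            "precision": precision,
            "specificity": specificity,
            "balanced_accuracy": balanced,
            "f1": f1,
        },
        index=pd.Index(cm.labels, name="class"),
    )


def overall_metrics(cm: ConfusionMatrix) -> dict:
    """Micro, macro and support-weighted summaries plus the multiclass MCC."""
    tp, fp, fn, tn = _ovr_counts(cm)
    per = per_class_metrics(cm)
    sup = cm.supports.astype(float)
    out: dict[str, float] = {}

    tp_s, fp_s, fn_s, tn_s = tp.sum(), fp.sum(), fn.sum(), tn.sum()
    out["micro_recall"] = float(tp_s / (tp_s + fn_s)) if tp_s + fn_s else float("nan")
    out["micro_precision"] = float(tp_s / (tp_s + fp_s)) if tp_s + fp_s else float("nan")
    mr, mp = out["micro_recall"], out["micro_precision"]
    out["micro_f1"] = float(2 * mr * mp / (mr + mp)) if (mr + mp) else float("nan")
    out["micro_specificity"] = float(tn_s / (tn_s + fp_s)) if tn_s + fp_s else float("nan")
    out["micro_balanced_accuracy"] = (out["micro_recall"] + out["micro_specificity"]) / 2.0
    out["accuracy"] = float(np.trace(cm.counts) / cm.total) if cm.total else float("nan")

    excluded = 0
    for col in ("recall", "precision", "specificity", "balanced_accuracy", "f1"):
        vals = per[col].to_numpy(dtype=float)
        defined = np.isfinite(vals)
        excluded = max(excluded, int((~defined).sum()))
        out[f"macro_{col}"] = float(np.mean(vals[defined])) if defined.any() else float("nan")
        w = sup[defined]
        out[f"weighted_{col}"] = (
            float(np.sum(vals[defined] * w) / w.sum()) if w.sum() else float("nan")
        )
    out["macro_excluded_classes"] = excluded
    out["mcc"] = multiclass_mcc(cm)
    return out


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """K-class Matthews correlation coefficient from confusion-matrix marginals.

    (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)) with
    c = trace, s = total, p_k = column sums, t_k = row sums. A degenerate
    denominator (all true or all predicted in one class) yields 0.
    """
    counts = cm.counts.astype(float)
    s = counts.sum()
    c = np.trace(counts)
    t = counts.sum(axis=1)
    p = counts.sum(axis=0)
    num = c * s - float(p @ t)
    den = np.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0:
        warnings.warn("degenerate confusion matrix; MCC set to 0", stacklevel=2)
        return 0.0
    return float(num / den)


def metrics_report(true_labels, predicted_labels, labels=None) -> dict:
    """Convenience wrapper: confusion + per-class + overall in one call."""
    cm = confusion(true_labels, predicted_labels, labels=labels)
    return {
        "confusion": cm,
        "per_class": per_class_metrics(cm),
        "overall": overall_metrics(cm),
    }
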