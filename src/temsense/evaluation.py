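"""Classifier evaluation: confusion matrices and every derived metric.

All metrics are defined on a 4x4 confusion matrix in the fixed class
order (relaxed, sad, happy, angry), rows = actual and columns =
predicted, or on per-instance class-probability vectors:

* accuracy (%) = 100 x trace / n
* Cohen's kappa = (p_o - p_e) / (1 - p_e), chance agreement p_e from
  the row/column marginals
* per-class sensitivity (recall), specificity, precision and F-score
* nominal-class error statistics MAE/RMSE and their relative forms
  RAE/RRSE (%), computed between predicted probability vectors and 0/1
  truth indicators, with the prior-predicting classifier as the
  reference for the relative forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion_classify import CVResult
from .labeling import EMOTIONS

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "cohen_kappa",
    "per_class_rates",
    "precision_recall_f",
    "nominal_error_stats",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 4x4 counts, rows = actual class, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = EMOTIONS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.classes)
        if c.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {c.shape}")
        if np.any(c < 0) or c.sum() == 0:
            raise ValueError("counts must be nonnegative with a positive total")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        """Read a bare 4x4 count matrix (no header) in canonical order."""
        counts = pd.read_csv(path, header=None).to_numpy()
        return cls(counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(cv: CVResult) -> ConfusionMatrix:
    """Tally cross-validated predictions into a confusion matrix."""
    if len(cv) == 0:
        raise ValueError("empty CV result")
    k = len(cv.classes)
    counts = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(cv.classes)}
    for t, p in zip(cv.y_true, cv.y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, cv.classes)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent."""
    return 100.0 * np.trace(cm.counts) / cm.n


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between actual and predicted classes."""
    n = cm.n
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / n**2
    if p_e == 1:
        raise ZeroDivisionError("expected agreement is 1; kappa undefined")
    return (p_o - p_e) / (1 - p_e)


def per_class_rates(cm: ConfusionMatrix) -> pd.DataFrame:
    """Sensitivity (true-positive rate) and specificity per class.

    Classes with no actual instances get NaN sensitivity.  Values are
    fractions in [0, 1].
    """
    c = cm.counts
    n = cm.n
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    diag = np.diag(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(rows > 0, diag / rows, np.nan)
    fp = cols - diag
    tn = n - rows - fp
    specificity = tn / (tn + fp)
    return pd.DataFrame(
        {"sensitivity": sensitivity, "specificity": specificity},
        index=list(cm.classes),
    )


def precision_recall_f(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall and F-score, plus weighted averages.

    Zero-denominator classes (never predicted, or never present) score 0
    with a warning.  The returned frame has one row per class and a
    final ``weighted_avg`` row (weights = actual class counts).
    """
    c = cm.counts
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    diag = np.diag(c)
    if np.any(cols == 0) or np.any(rows == 0):
        warnings.warn("class never predicted or never present: score reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cols > 0, diag / cols, 0.0)
        recall = np.where(rows > 0, diag / rows, 0.0)
        denom = precision + recall
        f = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    weights = rows / cm.n
    out = pd.DataFrame(
        {"precision": precision, "recall": recall, "f_score": f},
        index=list(cm.classes),
    )
    out.loc["weighted_avg"] = [precision @ weights, recall @ weights, f @ weights]
    return out


def nominal_error_stats(
    cv: CVResult, class_priors: np.ndarray | None = None
) -> dict[str, float]:
    """MAE, RMSE, RAE (%) and RRSE (%) of the class-probability output.

    With predicted probabilities ``p`` and 0/1 truth indicators ``y``
    over N instances and C classes, MAE and RMSE average |p - y| and
    (p - y)^2 over all N x C entries; RAE and RRSE express the same
    errors relative to a reference predictor that always outputs the
    training-fold class priors ``q`` (100% = no better than the priors).

    ``class_priors`` overrides the per-instance priors recorded in the
    CV result (one vector applied to every instance).
    """
    p = np.asarray(cv.proba, dtype=float)
    n, k = p.shape
    y = np.zeros_like(p)
    index = {c: i for i, c in enumerate(cv.classes)}
    for i, t in enumerate(cv.y_true):
        y[i, index[t]] = 1.0
    if class_priors is not None:
        q = np.tile(np.asarray(class_priors, dtype=float), (n, 1))
    else:
        q = np.asarray(cv.priors, dtype=float)
    if q.shape != p.shape:
        raise ValueError("priors must match the probability array shape")
    abs_err = np.abs(p - y)
    sq_err = (p - y) ** 2
    abs_ref = np.abs(q - y)
    sq_ref = (q - y) ** 2
    return {
        "mae": float(abs_err.mean()),
        "rmse": float(np.sqrt(sq_err.mean())),
        "rae_pct": float(100.0 * abs_err.sum() / abs_ref.sum()),
        "rrse_pct": float(100.0 * np.sqrt(sq_err.sum() / sq_ref.sum())),
    }


def metric_report(cv: CVResult) -> dict:
    """Full evaluation of one cross-validation run, as a JSON-ready dict."""
    cm = confusion(cv)
    rates = per_class_rates(cm)
    prf = precision_recall_f(cm)
    report = {
        "n": cm.n,
        "accuracy_pct": accuracy(cm),
        "kappa": cohen_kappa(cm),
        **nominal_error_stats(cv),
        "confusion": cm.counts.tolist(),
        "classes": list(cm.classes),
        "per_class": {
            c: {
                "sensitivity": _none_if_nan(rates.loc[c, "sensitivity"]),
                "specificity": _none_if_nan(rates.loc[c, "specificity"]),
                "precision": float(prf.loc[c, "precision"]),
                "recall": float(prf.loc[c, "recall"]),
                "f_score": float(prf.loc[c, "f_score"]),
            }
            for c in cm.classes
        },
        "weighted_avg": {
            k: float(prf.loc["weighted_avg", k])
            for k in ("precision", "recall", "f_score")
        },
    }
    return report


def _none_if_nan(x) -> float | None:
    return None if np.isnan(x) else float(x)
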