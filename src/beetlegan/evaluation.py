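"""Confusion matrix and the reported classification metrics.

All metrics derive from the 3x3 confusion matrix alone (rows = true class,
columns = predicted): overall accuracy, macro-averaged precision and recall,
Cohen's kappa, and macro F1/F2. F-beta weights recall beta^2 times as heavily
as precision; F2 matters here because missing a declining tree costs more
than a false alarm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    confusion: np.ndarray        # (3, 3) int, rows true / cols predicted
    accuracy: float
    precision_macro: float
    recall_macro: float
    kappa: float
    f1_macro: float
    f2_macro: float

    def as_percent(self) -> dict[str, float]:
        """Metrics scaled x100 for presentation (87.5 rather than 0.875)."""
        d = asdict(self)
        d.pop("confusion")
        return {k: round(100.0 * v, 1) for k, v in d.items()}

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def confusion_matrix(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    """Entry (i, j) counts samples with true class i predicted as j."""
    t = np.asarray(y_true, dtype=np.int64).ravel()
    p = np.asarray(y_pred, dtype=np.int64).ravel()
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    empty = den == 0
    if np.any(empty):
        log.warning("%s undefined for class(es) %s (empty denominator); "
                    "contributing 0", what, np.flatnonzero(empty).tolist())
    np.divide(num, den, out=out, where=~empty)
    return out


def metrics_report(confusion: np.ndarray) -> MetricsReport:
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.shape != (3, 3) or np.any(cm < 0):
        raise ValueError(f"confusion must be 3x3 nonnegative, got {cm.shape}")
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix is all zero")
    diag = np.diag(cm)
    row = cm.sum(axis=1)                 # true-class counts
    col = cm.sum(axis=0)                 # predicted-class counts
    accuracy = diag.sum() / n
    precision = _safe_div(diag, col, "precision")
    recall = _safe_div(diag, row, "recall")
    p_e = float((row * col).sum()) / (n * n)
    kappa = 0.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)

    def f_beta(beta: float) -> float:
        b2 = beta * beta
        den = b2 * precision + recall
        f = _safe_div((1 + b2) * precision * recall, den, f"F{beta:g}")
        return float(f.mean())

    return MetricsReport(
        confusion=np.asarray(confusion, dtype=np.int64),
        accuracy=float(accuracy),
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        kappa=float(kappa),
        f1_macro=f_beta(1.0),
        f2_macro=f_beta(2.0),
    )


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    return metrics_report(confusion_matrix(y_true, y_pred))


def format_report(report: MetricsReport) -> str:
    lines = ["confusion (rows=true, cols=predicted):"]
    for r in report.confusion:
        lines.append("  " + "  ".join(f"{v:5d}" for v in r))
    for k, v in report.as_percent().items():
        lines.append(f"{k}: {v:.1f}")
    return "\n".join(lines)
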