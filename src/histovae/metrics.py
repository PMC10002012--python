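"""Binary-classification evaluation battery.

Confusion matrix, precision, recall (sensitivity), F1, specificity, Cohen's
kappa and ROC AUC for the two-class patch problem.  Per-class precision/
recall/F1/specificity are combined across the two classes by
support-weighted averaging (each class weighted by its true-sample count),
which is what makes a constant predictor on a near-balanced truth produce
the characteristic degenerate values (weighted precision = prevalence^2,
weighted recall = prevalence).  ROC AUC uses the rank-based Mann-Whitney
estimator with midrank tie handling, equivalent to the trapezoidal area
under the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "precision_recall_f1_specificity",
    "cohens_kappa",
    "roc_auc",
    "evaluate",
    "REPORT_ROWS",
]

# Row labels of the comparison-report schema, in order.
REPORT_ROWS = (
    "Loss",
    "Accuracy",
    "Precision",
    "Recall or Sensitivity",
    "F1 Score",
    "Specificity",
    "Cohen's Kappa",
    "ROC AUC",
)


@dataclass
class ConfusionMatrix:
    """2x2 count grid indexed (true class, predicted class)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be a nonnegative 2x2 grid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self, label: int) -> dict:
        """TP/FP/FN/TN treating ``label`` as the positive class."""
        tp = self.counts[label, label]
        fn = self.counts[label].sum() - tp
        fp = self.counts[:, label].sum() - tp
        tn = self.total - tp - fn - fp
        return {"tp": int(tp), "fp": int(fp), "fn": int(fn), "tn": int(tn)}

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class MetricReport:
    loss: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    kappa: float
    roc_auc: float
    averaging: str = "weighted"

    def as_rows(self) -> dict:
        """Values keyed by the canonical report row labels."""
        return dict(
            zip(
                REPORT_ROWS,
                (self.loss, self.accuracy, self.precision, self.recall,
                 self.f1, self.specificity, self.kappa, self.roc_auc),
            )
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _check_labels(y, name):
    y = np.asarray(y)
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return y.astype(np.int64)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = _check_labels(y_true, "y_true")
    y_pred = _check_labels(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def _safe_div(num, den, what):
    if den == 0:
        logger.debug("zero denominator in %s; returning 0", what)
        return 0.0
    return num / den


def precision_recall_f1_specificity(cm: ConfusionMatrix, averaging: str = "weighted"):
    """Per-class precision/recall/F1/specificity combined across both classes.

    ``averaging="weighted"`` (default) weights each class by its support;
    ``"macro"`` is the unweighted mean.  A per-class value with a zero
    denominator is taken as 0.
    """
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = {}
    for label in (0, 1):
        c = cm.per_class(label)
        prec = _safe_div(c["tp"], c["tp"] + c["fp"], f"precision[{label}]")
        rec = _safe_div(c["tp"], c["tp"] + c["fn"], f"recall[{label}]")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"f1[{label}]")
        spec = _safe_div(c["tn"], c["fp"] + c["tn"], f"specificity[{label}]")
        per_class[label] = (prec, rec, f1, spec)
    if averaging == "weighted":
        weights = cm.support / cm.total
    else:
        weights = np.array([0.5, 0.5])
    stacked = np.array([per_class[0], per_class[1]])  # (class, metric)
    prec, rec, f1, spec = weights @ stacked
    return float(prec), float(rec), float(f1), float(spec)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (P0 - Pe) / (1 - Pe).

    P0 is the observed agreement (accuracy); Pe the agreement expected by
    chance from the row/column marginals.  Returns 0 when Pe = 1 (both
    marginals degenerate), where kappa is undefined.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p0 = cm.counts.trace() / n
    pe = float((cm.counts.sum(axis=1) / n) @ (cm.counts.sum(axis=0) / n))
    if pe >= 1.0 - 1e-15:
        logger.warning("chance agreement Pe = 1; kappa undefined, returning 0")
        return 0.0
    return float((p0 - pe) / (1.0 - pe))


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC with midrank ties: P(score+ > score-) + P(=)/2."""
    y_true = _check_labels(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    if len(y_true) != len(scores):
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC AUC")
    ranks = rankdata(scores)  # average (mid) ranks
    rank_sum_pos = float(ranks[y_true == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate(y_true, y_pred, scores, loss: float = float("nan"),
             averaging: str = "weighted") -> MetricReport:
    """Assemble the full metric battery for one experimental arm."""
    cm = confusion(y_true, y_pred)
    prec, rec, f1, spec = precision_recall_f1_specificity(cm, averaging)
    return MetricReport(
        loss=float(loss),
        accuracy=float(cm.counts.trace() / cm.total),
        precision=prec,
        recall=rec,
        f1=f1,
        specificity=spec,
        kappa=cohens_kappa(cm),
        roc_auc=roc_auc(y_true, scores),
        averaging=averaging,
    )
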