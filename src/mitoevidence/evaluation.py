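"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, CV.

Internal metric values are kept at full precision as proportions in [0, 1];
:func:`MetricsReport.as_percentages` rounds half-up to two decimals only at
the reporting layer.  Undefined ratios (zero denominators) are ``None``, not
zero.  ROC curves sweep the unique score values with tied scores moving as a
block, and AUC is the trapezoid area, which equals the Mann-Whitney pair
statistic with ties counted one half.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .io_model import (
    FeatureMatrix,
    Label,
    ProteinCatalog,
    ValidationError,
)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "confusion_metrics",
    "roc_curve",
    "select_threshold",
    "kfold_cv",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValidationError("all-zero confusion matrix")

    @property
    def actual_positives(self) -> int:
        return self.tp + self.fn

    @property
    def actual_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Proportions in [0,1]; ``None`` where the ratio is undefined."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    fdr: float | None

    def as_percentages(self, ndigits: int = 2) -> dict[str, float | None]:
        """Half-up rounded percentages, e.g. 0.846696 -> 84.67."""
        q = Decimal(1).scaleb(-ndigits)

        def pct(v: float | None) -> float | None:
            if v is None:
                return None
            return float(Decimal(repr(v * 100)).quantize(q, rounding=ROUND_HALF_UP))

        return {
            "accuracy": pct(self.accuracy),
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "fpr": pct(self.fpr),
            "fdr": pct(self.fdr),
        }


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard binary-classification metrics from a confusion matrix."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricsReport(
        accuracy=ratio(cm.tp + cm.tn, cm.total),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.fp + cm.tn),
        fpr=ratio(cm.fp, cm.fp + cm.tn),
        fdr=ratio(cm.fp, cm.tp + cm.fp),
    )


@dataclass
class ROCCurve:
    """Operating points swept over thresholds, with trapezoid AUC.

    A score is called positive when it is strictly greater than the
    threshold, matching the integration stage's classification rule.  Points
    are sorted by ascending threshold, so TPR and FPR are non-increasing.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over the unique score values (ties move as a block).

    ``labels`` is boolean/0-1 truth; both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_curve requires both classes")
    uniq = np.unique(scores)  # ascending
    # thresholds: just below the minimum (everything positive) then each
    # unique score (strict >, so at threshold = max nothing is positive)
    thresholds = np.concatenate(([-np.inf], uniq))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores > t
        tpr[i] = (called & labels).sum() / n_pos
        fpr[i] = (called & ~labels).sum() / n_neg
    # trapezoid over the (FPR, TPR) staircase; points run from (1,1) to (0,0)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCCurve(thresholds, fpr, tpr, auc, n_pos, n_neg)


def select_threshold(
    roc: ROCCurve,
    criterion: str = "max_accuracy",
    fpr_cap: float | None = None,
) -> float:
    """Pick an operating threshold from a ROC curve.

    criterion:
      * ``max_accuracy`` — maximize (TPR*P + (1-FPR)*N) / (P+N); ties break
        toward the larger (more conservative) threshold.
      * ``max_youden`` — maximize TPR - FPR; same tie rule.
      * ``fpr_cap`` — smallest threshold with FPR <= ``fpr_cap``.
    """
    t, tpr, fpr = roc.thresholds, roc.tpr, roc.fpr
    if len(t) == 0:
        raise ValidationError("empty ROC curve")
    if criterion == "fpr_cap":
        if fpr_cap is None:
            raise ValidationError("fpr_cap criterion requires a cap value")
        ok = np.flatnonzero(fpr <= fpr_cap)
        if ok.size == 0:
            raise ValidationError(f"no threshold achieves FPR <= {fpr_cap}")
        return float(t[ok[0]])  # thresholds ascend; first feasible is smallest
    if criterion == "max_accuracy":
        objective = (tpr * roc.n_pos + (1.0 - fpr) * roc.n_neg) / (
            roc.n_pos + roc.n_neg
        )
    elif criterion == "max_youden":
        objective = tpr - fpr
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")
    best = np.flatnonzero(objective == objective.max())
    return float(t[best[-1]])  # largest threshold among ties


def kfold_cv(
    features: FeatureMatrix,
    catalog: ProteinCatalog,
    k: int = 10,
    alpha: float = 1.0,
    threshold: float = 1.37,
    seed: int = 0,
    missing_policy: str = "skip",
) -> MetricsReport:
    """Stratified k-fold cross-validation of the naive Bayes integration.

    Likelihood ratios are re-estimated on each training split and the
    held-out proteins scored and thresholded; the report pools the held-out
    confusion counts over all folds.  Folds are stratified by label so both
    classes appear in every fold at gold-standard class ratios.
    """
    from sklearn.model_selection import StratifiedKFold

    from .bayes_integration import classify, estimate_likelihood_ratios, integrate

    if k < 2:
        raise ValidationError("k must be >= 2")
    labels = catalog.labels
    idx, y = [], []
    for i, pid in enumerate(features.protein_ids):
        lab = labels.get(pid)
        if lab is Label.POSITIVE:
            idx.append(i)
            y.append(1)
        elif lab is Label.NEGATIVE:
            idx.append(i)
            y.append(0)
    idx = np.array(idx)
    y = np.array(y)
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ValidationError("a class is too small for stratified k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = fn = tn = 0
    for train_rows, test_rows in skf.split(idx, y):
        train_ids = {features.protein_ids[i] for i in idx[train_rows]}
        train_catalog = ProteinCatalog(
            [e for e in catalog.entries if e[0] in train_ids]
        )
        lr = estimate_likelihood_ratios(features, train_catalog, alpha=alpha)
        test_idx = idx[test_rows]
        test_fm = FeatureMatrix(
            [features.protein_ids[i] for i in test_idx],
            list(features.predictor_ids),
            features.calls[test_idx],
        )
        scores = integrate(test_fm, lr, missing_policy=missing_policy)
        calls = classify(scores, threshold)
        truth = y[test_rows].astype(bool)
        tp += int((calls & truth).sum())
        fp += int((calls & ~truth).sum())
        fn += int((~calls & truth).sum())
        tn += int((~calls & ~truth).sum())
    return confusion_metrics(ConfusionMatrix(tp, fp, fn, tn))
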