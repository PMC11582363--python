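"""Multi-class evaluation metrics for stage prediction.

Per-stage one-vs-rest confusion counts feed the usual derived metrics
(precision, sensitivity, specificity, F-score), averaged unweighted across
classes.  Chance-corrected agreement is Cohen's kappa
(P_o − P_e)/(1 − P_e); distributional drift between predicted and reference
class distributions is the Kullback–Leibler divergence Σ p·log(p/q) (always
≥ 0; a ``paper_sign`` flag flips the orientation to the printed-integrand
form, which is its negative); discrimination is one-vs-rest ROC-AUC with
midrank tie handling.  Zero denominators yield 0 with a structured warning
instead of raising, so small cross-validation folds never abort a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import rel_entr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "basic_metrics",
    "kappa",
    "kl_divergence",
    "roc_auc",
    "stratified_kfold",
    "evaluate_predictions",
    "MetricWarning",
    "LabelError",
]


class LabelError(ValueError):
    """A label outside the declared class set."""


class MetricWarning(UserWarning):
    """A metric denominator was zero; the metric was reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class; each row sums to n."""

    classes: tuple
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass
class MetricsReport:
    """Per-class and macro metrics; macro = unweighted class mean."""

    classes: tuple
    precision: dict
    sensitivity: dict
    specificity: dict
    f_score: dict
    accuracy: float
    macro_precision: float
    macro_sensitivity: float
    macro_specificity: float
    macro_f_score: float
    kappa: float | None = None
    p_observed: float | None = None
    p_expected: float | None = None
    kl_divergence: float | None = None
    roc_auc: dict = field(default_factory=dict)
    macro_roc_auc: float | None = None

    def to_dict(self) -> dict:
        cls_key = lambda c: str(c)
        return {
            "classes": [cls_key(c) for c in self.classes],
            "per_class": {
                cls_key(c): {
                    "precision": self.precision[c],
                    "sensitivity": self.sensitivity[c],
                    "specificity": self.specificity[c],
                    "f_score": self.f_score[c],
                    **(
                        {"roc_auc": self.roc_auc[c]}
                        if c in self.roc_auc
                        else {}
                    ),
                }
                for c in self.classes
            },
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "sensitivity": self.macro_sensitivity,
                "specificity": self.macro_specificity,
                "f_score": self.macro_f_score,
                "roc_auc": self.macro_roc_auc,
            },
            "kappa": self.kappa,
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "kl_divergence": self.kl_divergence,
        }


def confusion(y_true, y_pred, classes: Sequence | None = None) -> ConfusionCounts:
    """One-vs-rest confusion counts per class.

    Raises
    ------
    LabelError
        A label not in ``classes``, or empty inputs.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise LabelError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise LabelError("y_true and y_pred lengths differ")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    classes = tuple(classes)
    known = set(classes)
    unseen = (set(y_true.tolist()) | set(y_pred.tolist())) - known
    if unseen:
        raise LabelError(f"labels outside declared classes: {sorted(unseen)}")
    tp = np.empty(len(classes), int)
    fp = np.empty(len(classes), int)
    fn = np.empty(len(classes), int)
    tn = np.empty(len(classes), int)
    for k, c in enumerate(classes):
        pt = y_true == c
        pp = y_pred == c
        tp[k] = int(np.sum(pt & pp))
        fp[k] = int(np.sum(~pt & pp))
        fn[k] = int(np.sum(pt & ~pp))
        tn[k] = int(np.sum(~pt & ~pp))
    return ConfusionCounts(classes, tp, fp, fn, tn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", MetricWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def basic_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
    TN/(TN+FP), and F = 2PR/(P+R), per class and macro-averaged."""
    precision, sensitivity, specificity, f_score = {}, {}, {}, {}
    for k, c in enumerate(counts.classes):
        tp, fp, fn, tn = (int(counts.tp[k]), int(counts.fp[k]),
                          int(counts.fn[k]), int(counts.tn[k]))
        p = _safe_div(tp, tp + fp, f"precision[{c}]")
        r = _safe_div(tp, tp + fn, f"sensitivity[{c}]")
        precision[c] = p
        sensitivity[c] = r
        specificity[c] = _safe_div(tn, tn + fp, f"specificity[{c}]")
        f_score[c] = _safe_div(2.0 * p * r, p + r, f"f_score[{c}]")
    n = counts.n
    accuracy = float(counts.tp.sum()) / n if n else 0.0
    macro = lambda d: float(np.mean(list(d.values())))
    return MetricsReport(
        classes=counts.classes,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f_score=f_score,
        accuracy=accuracy,
        macro_precision=macro(precision),
        macro_sensitivity=macro(sensitivity),
        macro_specificity=macro(specificity),
        macro_f_score=macro(f_score),
    )


def kappa(y_true, y_pred) -> tuple[float, float, float]:
    """Cohen's kappa with its components.

    Returns (kappa, P_o, P_e); P_o is the observed agreement rate and
    P_e = Σ_c marginal_true(c) · marginal_pred(c).  When P_e = 1 (both
    raters constant and equal) kappa is undefined and NaN is returned
    with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise LabelError("need equal-length, non-empty label vectors")
    n = y_true.size
    p_o = float(np.mean(y_true == y_pred))
    classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    p_e = float(
        sum(
            np.sum(y_true == c) / n * np.sum(y_pred == c) / n
            for c in classes
        )
    )
    if p_e >= 1.0 - 1e-15:
        warnings.warn("kappa undefined: expected agreement is 1",
                      MetricWarning, stacklevel=2)
        return float("nan"), p_o, p_e
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def kl_divergence(p, q, paper_sign: bool = False) -> float:
    """Discrete KL divergence Σ p·log(p/q) in nats.

    Terms with p = 0 contribute 0; q = 0 where p > 0 gives +inf.
    ``paper_sign`` returns the opposite orientation Σ p·log(q/p) (= −KL).

    Raises
    ------
    ValueError
        Inputs negative or not summing to 1 within 1e-9.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a shape")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("distributions must sum to 1 (within 1e-9)")
    val = float(np.sum(rel_entr(p, q)))
    return -val if paper_sign else val


def roc_auc(y_true, scores, classes: Sequence) -> tuple[dict, float]:
    """One-vs-rest ROC-AUC per class (midrank ties) and the macro mean.

    ``scores`` is an (n, n_classes) probability matrix in ``classes``
    column order.  Classes absent from ``y_true`` are reported as NaN and
    excluded from the macro average.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = tuple(classes)
    if scores.shape != (y_true.size, len(classes)):
        raise ValueError("scores must be (n, n_classes)")
    per_class = {}
    usable = []
    for k, c in enumerate(classes):
        pos = (y_true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == pos.size:
            per_class[c] = float("nan")
            continue
        per_class[c] = float(roc_auc_score(pos, scores[:, k]))
        usable.append(per_class[c])
    macro = float(np.mean(usable)) if usable else float("nan")
    return per_class, macro


def evaluate_predictions(
    y_true, y_pred, scores=None, classes: Sequence | None = None
) -> MetricsReport:
    """Full report: confusion-derived metrics + kappa + KL + ROC-AUC.

    The KL term compares the empirical class distribution of the
    predictions (Q) against that of the reference labels (P), with
    add-one-half smoothing on zero cells so the divergence stays finite.
    """
    counts = confusion(y_true, y_pred, classes)
    report = basic_metrics(counts)
    k, p_o, p_e = kappa(y_true, y_pred)
    report.kappa = k
    report.p_observed = p_o
    report.p_expected = p_e
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = y_true.size
    p_hist = np.array([np.sum(y_true == c) for c in counts.classes], float)
    q_hist = np.array([np.sum(y_pred == c) for c in counts.classes], float)
    if np.any(p_hist == 0) or np.any(q_hist == 0):
        p_hist = p_hist + 0.5
        q_hist = q_hist + 0.5
    report.kl_divergence = kl_divergence(p_hist / p_hist.sum(),
                                         q_hist / q_hist.sum())
    if scores is not None:
        per_class, macro = roc_auc(y_true, scores, counts.classes)
        report.roc_auc = per_class
        report.macro_roc_auc = macro
    return report


def stratified_kfold(
    ordinal,
    config=None,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[float], float, float]:
    """k-fold cross-validated LSTM accuracy with class-preserving folds.

    Returns (per-fold accuracies, mean, sd).  Each row lands in exactly
    one test fold; a class smaller than k raises a stratification error.
    """
    from .lstm import LSTMClassifier, LSTMConfig, _extract_xy
    from .infosys import InformationSystem
    from .rsfas import OrdinalSystem

    X, y, feats, classes = _extract_xy(ordinal)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot make {k} folds"
        )
    config = config or LSTMConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    is_ = ordinal.system if isinstance(ordinal, OrdinalSystem) else ordinal
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        sub = InformationSystem(
            object_ids=[is_.object_ids[i] for i in tr],
            attributes=list(is_.attributes),
            values=is_.values[tr],
            decision_attribute=is_.decision_attribute,
            time_attribute=is_.time_attribute,
            event_attribute=is_.event_attribute,
        )
        model = LSTMClassifier(config).fit(sub, split=(1.0, 0.0))
        labels, _ = model.predict(X[te])
        accs.append(float(np.mean(labels == classes[y[te]])))
    return accs, float(np.mean(accs)), float(np.std(accs))
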