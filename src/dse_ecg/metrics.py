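"""Evaluation suite: confusion matrix, per-class F1, macro F1,
accuracy/sensitivity/specificity, and grouped sub-abnormal F1.

All per-class quantities are one-vs-rest on the 9×9 confusion matrix
(rows = reference label, columns = prediction, fixed class order). With TP,
FP, FN, TN the one-vs-rest counts of class i:

    F1_i  = 2·Fp·Fr / (Fp + Fr),  Fp = TP/(TP+FP),  Fr = TP/(TP+FN)
    Acc_i = (TP+TN) / (TP+TN+FP+FN)
    Se_i  = TP / (TP+FN)          (numerically identical to recall Fr)
    Sp_i  = TN / (TN+FP)

Macro F1 is the unweighted mean of the nine F1_i. The four sub-abnormal
scores (AF; Block = I-AVB∪LBBB∪RBBB; PC = PAC∪PVC; ST = STD∪STE) merge the
member rows/columns of the confusion matrix into a super-class and score it
one-vs-rest — within-group confusions therefore do not count as errors.

Convention: an F1/ratio with an empty denominator is reported as 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .records import CLASSES, SUBABNORMAL_GROUPS


def confusion(
    references: Sequence[str],
    predictions: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> np.ndarray:
    """9×9 confusion matrix with rows = reference, columns = prediction."""
    if len(references) != len(predictions):
        raise ValueError("references and predictions differ in length")
    for lab in (*references, *predictions):
        if lab not in classes:
            raise ValueError(f"unknown label {lab!r}")
    return _sk_confusion(references, predictions, labels=list(classes))


def _ovr_counts(cm: np.ndarray, i: int) -> tuple[float, float, float, float]:
    tp = cm[i, i]
    fp = cm[:, i].sum() - tp
    fn = cm[i, :].sum() - tp
    tn = cm.sum() - tp - fp - fn
    return float(tp), float(fp), float(fn), float(tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def f1_per_class(cm: np.ndarray) -> np.ndarray:
    """One-vs-rest F1 for every class (harmonic mean of precision/recall)."""
    cm = np.asarray(cm)
    out = np.zeros(cm.shape[0])
    for i in range(cm.shape[0]):
        tp, fp, fn, _ = _ovr_counts(cm, i)
        fp_rate = _safe_div(tp, tp + fp)
        fr_rate = _safe_div(tp, tp + fn)
        out[i] = _safe_div(2 * fp_rate * fr_rate, fp_rate + fr_rate)
    return out


def macro_f1(per_class: Sequence[float]) -> float:
    """Unweighted mean of the per-class F1 scores."""
    per_class = np.asarray(per_class, dtype=np.float64)
    return float(per_class.mean())


def acc_se_sp(cm: np.ndarray) -> np.ndarray:
    """Per-class (accuracy, sensitivity, specificity) triples, one-vs-rest."""
    cm = np.asarray(cm)
    out = np.zeros((cm.shape[0], 3))
    for i in range(cm.shape[0]):
        tp, fp, fn, tn = _ovr_counts(cm, i)
        out[i, 0] = _safe_div(tp + tn, tp + tn + fp + fn)
        out[i, 1] = _safe_div(tp, tp + fn)
        out[i, 2] = _safe_div(tn, tn + fp)
    return out


def merge_confusion(
    cm: np.ndarray,
    group: Sequence[str],
    classes: Sequence[str] = CLASSES,
) -> np.ndarray:
    """Merge the rows/columns of `group` members into one leading super-class.

    Returns an (m+1)×(m+1) matrix whose row/column 0 is the merged group and
    whose remaining axes are the non-member classes in original order. Row
    and column totals are conserved.
    """
    cm = np.asarray(cm)
    idx = [classes.index(g) for g in group]
    rest = [i for i in range(len(classes)) if i not in idx]
    order = [idx, *[[i] for i in rest]]
    m = len(order)
    out = np.zeros((m, m), dtype=cm.dtype)
    for a, rows in enumerate(order):
        for b, cols in enumerate(order):
            out[a, b] = cm[np.ix_(rows, cols)].sum()
    return out


def subabnormal_f1(
    cm: np.ndarray,
    groups: Mapping[str, Sequence[str]] = SUBABNORMAL_GROUPS,
    classes: Sequence[str] = CLASSES,
) -> dict[str, float]:
    """F1 of each sub-abnormal super-class after confusion-matrix merging."""
    members: list[str] = []
    for g in groups.values():
        for cls in g:
            if cls in members:
                raise ValueError(f"class {cls!r} appears in more than one group")
            members.append(cls)
    out = {}
    for name, group in groups.items():
        merged = merge_confusion(cm, group, classes)
        out[name] = float(f1_per_class(merged)[0])
    return out


@dataclass
class MetricsReport:
    """Full evaluation of one prediction set against references."""

    confusion: np.ndarray
    classes: tuple[str, ...] = CLASSES
    per_class_f1: np.ndarray = field(init=False)
    macro_f1: float = field(init=False)
    acc: np.ndarray = field(init=False)
    se: np.ndarray = field(init=False)
    sp: np.ndarray = field(init=False)
    subabnormal: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion)
        if cm.ndim != 2 or cm.shape != (len(self.classes), len(self.classes)):
            raise ValueError(f"confusion matrix shape {cm.shape} invalid")
        if (cm < 0).any():
            raise ValueError("confusion matrix has negative counts")
        self.per_class_f1 = f1_per_class(cm)
        self.macro_f1 = macro_f1(self.per_class_f1)
        triples = acc_se_sp(cm)
        self.acc, self.se, self.sp = triples[:, 0], triples[:, 1], triples[:, 2]
        self.subabnormal = subabnormal_f1(cm, classes=self.classes)

    @classmethod
    def from_labels(
        cls, references: Sequence[str], predictions: Sequence[str]
    ) -> "MetricsReport":
        return cls(confusion(references, predictions))

    def to_dict(self, ndigits: int = 3) -> dict:
        rnd = lambda v: round(float(v), ndigits)  # noqa: E731
        return {
            "macro_f1": rnd(self.macro_f1),
            "per_class": {
                c: {
                    "f1": rnd(self.per_class_f1[i]),
                    "acc": rnd(self.acc[i]),
                    "se": rnd(self.se[i]),
                    "sp": rnd(self.sp[i]),
                }
                for i, c in enumerate(self.classes)
            },
            "subabnormal_f1": {k: rnd(v) for k, v in self.subabnormal.items()},
            "confusion": np.asarray(self.confusion).tolist(),
            "n": int(np.asarray(self.confusion).sum()),
        }
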