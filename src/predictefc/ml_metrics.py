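"""Multi-label evaluation metrics.

Two measurement sets are provided.  For N samples with true labelsets ``L_k``
and predicted labelsets ``L_k*`` over M possible labels:

* overall measures — aiming (mean |intersection| / |predicted|), coverage
  (mean |intersection| / |true|), accuracy (mean Jaccard overlap), absolute
  true (exact-match / subset-accuracy rate) and absolute false (mean
  symmetric-difference size over M, i.e. the Hamming loss);
* per-class one-vs-rest binary measures — confusion counts plus accuracy,
  recall, precision, F1 and MCC, and the threshold-free AUROC / AUPR.

Conventions for degenerate denominators: MCC with a zero denominator is 0;
precision/recall with zero denominators are reported as 0 and flagged; AUROC
needs both a positive and a negative sample (else ``nan``), AUPR needs at
least one positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .annot_io import LabelTable

__all__ = [
    "OverallMetrics",
    "ClassMetrics",
    "PerClassMetrics",
    "overall_metrics",
    "per_class_metrics",
    "auroc",
    "aupr",
    "multiplicity_degree",
    "multiplicity_degree_from_counts",
]


@dataclass(frozen=True)
class OverallMetrics:
    """The five overall multi-label measures on N samples over M labels."""

    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    N: int
    M: int

    def as_dict(self) -> dict[str, float]:
        return {
            "aiming": self.aiming,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "absolute_false": self.absolute_false,
        }

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Table-shaped view, rounded the way result tables print."""
        return {k: round(v, ndigits) for k, v in self.as_dict().items()}


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest binary measures for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    mcc: float
    auroc: float  # nan when truth is single-class
    aupr: float  # nan when no positives
    precision_defined: bool
    recall_defined: bool

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1, "mcc": self.mcc,
            "auroc": self.auroc, "aupr": self.aupr,
        }


#: per-class metrics for classes 1..L, keyed by 1-based label index
PerClassMetrics = dict[int, ClassMetrics]


def _check_sets(true_sets, pred_sets):
    true_sets = [frozenset(int(l) for l in s) for s in true_sets]
    pred_sets = [frozenset(int(l) for l in s) for s in pred_sets]
    if len(true_sets) != len(pred_sets):
        raise ValueError("true_sets and pred_sets must have equal length")
    if not true_sets:
        raise ValueError("need at least one sample")
    if any(not s for s in true_sets):
        raise ValueError("every true labelset must be nonempty")
    return true_sets, pred_sets


def overall_metrics(true_sets, pred_sets, M: int) -> OverallMetrics:
    """Exact set arithmetic for the five overall measures.

    A sample with both the true and the predicted set empty would make the
    Jaccard term 0/0; nonempty true sets are required and the never-empty
    prediction rule upstream prevents empty predictions, but the condition is
    still checked defensively.
    """
    true_sets, pred_sets = _check_sets(true_sets, pred_sets)
    N = len(true_sets)
    aiming = coverage = accuracy = abs_true = abs_false = 0.0
    for t, p in zip(true_sets, pred_sets):
        inter = len(t & p)
        union = len(t | p)
        if union == 0:
            raise ValueError("true and predicted labelsets both empty (undefined overlap)")
        # aiming normalizes by the predicted set; an empty prediction contributes 0
        aiming += inter / len(p) if p else 0.0
        coverage += inter / len(t)
        accuracy += inter / union
        abs_true += 1.0 if t == p else 0.0
        abs_false += (union - inter) / M
    return OverallMetrics(
        aiming=aiming / N,
        coverage=coverage / N,
        accuracy=accuracy / N,
        absolute_true=abs_true / N,
        absolute_false=abs_false / N,
        N=N,
        M=M,
    )


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def per_class_metrics(true_sets, pred_sets, L: int, scores=None) -> PerClassMetrics:
    """One-vs-rest confusion counts and binary measures for each class 1..L.

    ``scores`` (optional, shape (N, L)) supplies per-label ranking scores for
    AUROC/AUPR; without it the curve areas are ``nan``.
    """
    true_sets, pred_sets = _check_sets(true_sets, pred_sets)
    N = len(true_sets)
    if scores is not None:
        scores = np.asarray(scores, float)
        if scores.shape != (N, L):
            raise ValueError(f"scores must have shape ({N}, {L})")
    out: PerClassMetrics = {}
    for j in range(1, L + 1):
        y_true = np.fromiter((j in t for t in true_sets), dtype=bool, count=N)
        y_pred = np.fromiter((j in p for p in pred_sets), dtype=bool, count=N)
        tp = int(np.sum(y_true & y_pred))
        fp = int(np.sum(~y_true & y_pred))
        tn = int(np.sum(~y_true & ~y_pred))
        fn = int(np.sum(y_true & ~y_pred))
        prec_def, rec_def = (tp + fp) > 0, (tp + fn) > 0
        a = np.nan
        pr = np.nan
        if scores is not None:
            s = scores[:, j - 1]
            a = auroc(s, y_true)
            pr = aupr(s, y_true)
        out[j] = ClassMetrics(
            tp=tp, fp=fp, tn=tn, fn=fn,
            accuracy=(tp + tn) / N,
            recall=tp / (tp + fn) if rec_def else 0.0,
            precision=tp / (tp + fp) if prec_def else 0.0,
            f1=2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0,
            mcc=_mcc(tp, fp, tn, fn),
            auroc=a,
            aupr=pr,
            precision_defined=prec_def,
            recall_defined=rec_def,
        )
    return out


def auroc(scores, truth) -> float:
    """Area under the ROC curve (Mann-Whitney rank statistic, mid-rank ties).

    Returns ``nan`` when the truth vector is single-class (undefined).
    """
    truth = np.asarray(truth, bool)
    if truth.all() or (~truth).all():
        return float("nan")
    return float(roc_auc_score(truth, np.asarray(scores, float)))


def aupr(scores, truth, variant: str = "average_precision") -> float:
    """Area under the precision-recall curve.

    ``variant="average_precision"`` (the headline number) is the step-wise sum
    of precision over recall increments; ``variant="trapezoid"`` integrates the
    PR points by the trapezoid rule, exported because curve integrators differ
    across toolkits.  ``nan`` when there are no positive samples.
    """
    truth = np.asarray(truth, bool)
    scores = np.asarray(scores, float)
    if not truth.any():
        return float("nan")
    if variant == "average_precision":
        return float(average_precision_score(truth, scores))
    if variant == "trapezoid":
        from sklearn.metrics import precision_recall_curve

        precision, recall, _ = precision_recall_curve(truth, scores)
        order = np.argsort(recall)
        return float(np.trapezoid(precision[order], recall[order]))
    raise ValueError(f"unknown variant {variant!r}")


def multiplicity_degree(labels: LabelTable) -> float:
    """Average number of labels per protein (>= 1)."""
    if len(labels) == 0:
        raise ValueError("empty label table")
    return sum(len(s) for s in labels.entries.values()) / len(labels)


def multiplicity_degree_from_counts(class_counts, n_distinct: int) -> float:
    """Multiplicity degree from a per-class assignment-count breakdown.

    ``class_counts`` are the per-class numbers of label assignments (a protein
    in two classes is counted once in each); ``n_distinct`` is the number of
    distinct proteins.
    """
    total = int(np.sum(np.asarray(class_counts, dtype=np.int64)))
    if n_distinct <= 0 or total < n_distinct:
        raise ValueError("need n_distinct >= 1 and total assignments >= n_distinct")
    return total / n_distinct
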