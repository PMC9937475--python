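"""ROC analysis and operating-point summaries for the LR observer.

Two routes to the detectability index Az are exposed: the empirical
(nonparametric, trapezoidal = Mann-Whitney) area from subject-level scores,
and the binormal closed form Phi(|mu_n - mu_d| / sqrt(sigma_n^2 + sigma_d^2))
from fitted Gaussian parameters.  AD is the positive class throughout and
scores are oriented so that larger means more diseased (the log-LR is).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CohortTable, Group
from .densities import GaussianDensity
from .errors import UndefinedIntervalError, UndefinedROCError
from .observer import DISEASED, LRObserverModel, classify


@dataclass
class ROCCurve:
    """An empirical ROC: (FPR, TPR) vertices from (0,0) to (1,1) plus area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts at a fixed operating point; AD is positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise UndefinedROCError("report needs at least one subject per class")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _as_binary_labels(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, Group):
            out.append(lab is Group.AD)
        elif isinstance(lab, str):
            token = lab.strip().lower()
            if token in ("diseased", "ad", "1", "positive"):
                out.append(True)
            elif token in ("normal", "nc", "0", "negative"):
                out.append(False)
            else:
                raise ValueError(f"unrecognized label {lab!r}")
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


def empirical_roc(scores, labels) -> ROCCurve:
    """Nonparametric ROC by threshold sweep over the unique scores.

    Tied scores collapse to single vertices; the trapezoidal area equals the
    Mann-Whitney statistic P(score_D > score_N) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("ROC needs at least one diseased and one normal subject")
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)),
                    n_pos=n_pos, n_neg=n_neg)


def binormal_az(normal: GaussianDensity, diseased: GaussianDensity) -> float:
    """Closed-form binormal area: Phi(|mu_n - mu_d| / sqrt(sn^2 + sd^2)).

    Equals the probability that a diseased draw lies on the diseased side of
    an independent normal draw.
    """
    sep = abs(normal.mu - diseased.mu) / float(np.hypot(normal.sigma, diseased.sigma))
    return float(norm.cdf(sep))


def auc_confidence_interval(curve: ROCCurve, level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation interval for the empirical area."""
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise UndefinedIntervalError("need at least 2 subjects per class for a CI")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    a = curve.auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (curve.n_pos - 1) * (q1 - a * a)
        + (curve.n_neg - 1) * (q2 - a * a)
    ) / (curve.n_pos * curve.n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(norm.ppf(0.5 + level / 2))
    return max(0.0, a - z * se), min(1.0, a + z * se)


def evaluate_at_zero_threshold(
    model: LRObserverModel, test: CohortTable
) -> ClassificationReport:
    """Classify every test subject at the y=0 criterion and tally the counts."""
    if len(test) == 0:
        raise UndefinedROCError("empty test table")
    tp = fp = tn = fn = 0
    for rec in test:
        if rec.group is Group.UNKNOWN:
            raise UndefinedROCError(
                f"test subject {rec.subject_id!r} has no AD/NC label"
            )
        called_diseased = classify(model, rec).decision == DISEASED
        if rec.group is Group.AD:
            tp += called_diseased
            fn += not called_diseased
        else:
            fp += called_diseased
            tn += not called_diseased
    return ClassificationReport(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
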