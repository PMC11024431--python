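"""Diagnostic evaluation: confusion-matrix metrics, ROC AUC, threshold
sweeps, constrained-Youden threshold selection, and the MMSE-cutoff
benchmark.

Conventions: a participant is called positive (impaired) when the model
score is greater than or equal to the threshold; Youden's J is
sensitivity + specificity - 1; the F-score is the harmonic mean of
precision and sensitivity; MSE is the mean squared difference between the
probabilistic score and the binary label.  For the MMSE comparison a
participant screens positive when their MMSE score is strictly below the
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

#: Thresholds scanned by :func:`threshold_sweep`: 0.00 to 1.00 step 0.01.
THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)


class EvaluationError(ValueError):
    """Raised for degenerate evaluation inputs (e.g. a single-class set)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricSet:
    """The evaluation metric suite; ``auc``/``mse`` are None when the inputs
    (probabilistic scores) needed to compute them were not supplied."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    youden_j: float
    auc: float | None = None
    mse: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_score": self.f_score,
            "youden_j": self.youden_j,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.mse is not None:
            d["mse"] = self.mse
        return d


def metrics_from_confusion(c: ConfusionMatrix) -> MetricSet:
    """Threshold metrics from counts.  Requires at least one member of each
    class; precision and F-score are 0 when undefined (no positive calls)."""
    if c.tp + c.fn == 0:
        raise EvaluationError("no positive (impaired) participants in the set")
    if c.tn + c.fp == 0:
        raise EvaluationError("no negative (cognitively normal) participants in the set")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    f = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.n,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_score=f,
        youden_j=sens + spec - 1.0,
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2):
    the probability that a random positive outscores a random negative."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise EvaluationError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mse(scores, labels) -> float:
    """Mean squared error of probabilistic scores against binary labels."""
    s = np.asarray(scores, dtype=float)
    l = np.asarray(labels, dtype=float)
    return float(np.mean((s - l) ** 2))


def evaluate_scores(scores, labels, threshold: float) -> MetricSet:
    """Full metric suite for scores at a decision threshold (score >= t)."""
    labels = np.asarray(labels).astype(int)
    preds = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    base = metrics_from_confusion(ConfusionMatrix.from_predictions(labels, preds))
    return MetricSet(
        **{**base.as_dict()},
        auc=auc(scores, labels),
        mse=mse(scores, labels),
    )


def threshold_sweep(scores, labels) -> pd.DataFrame:
    """Metrics at each threshold 0.00..1.00 (101 rows, rule score >= t).

    Columns: threshold, accuracy, sensitivity, specificity, f_score,
    youden_j.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise EvaluationError("threshold sweep needs both classes present")
    rows = []
    for t in THRESHOLD_GRID:
        m = metrics_from_confusion(
            ConfusionMatrix.from_predictions(labels, (scores >= t).astype(int))
        )
        rows.append(
            {
                "threshold": t,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f_score": m.f_score,
                "youden_j": m.youden_j,
            }
        )
    return pd.DataFrame(rows)


def select_threshold(sweep: pd.DataFrame) -> tuple[float, bool]:
    """Constrained Youden threshold choice.

    Among thresholds where mean sensitivity is at least mean specificity,
    pick the one maximizing J = sensitivity + specificity - 1, taking the
    smallest threshold on ties (prioritizing sensitivity for a screening
    instrument).  The comparison is non-strict: on nearly separable CV
    scores sensitivity and specificity are both 1 over the whole interior,
    and a strict constraint would only be satisfiable at threshold 0
    (calling everyone impaired, J = 0).  If no threshold satisfies the
    constraint, fall back to the unconstrained argmax of J with a warning.

    Returns ``(threshold, constraint_satisfied)``.
    """
    if len(sweep) == 0:
        raise EvaluationError("empty threshold sweep")
    j = (sweep["sensitivity"] + sweep["specificity"] - 1.0).to_numpy()
    thr = sweep["threshold"].to_numpy(dtype=float)
    ok = (sweep["sensitivity"] >= sweep["specificity"]).to_numpy()
    if ok.any():
        jj = np.where(ok, j, -np.inf)
        return float(thr[int(np.argmax(jj))]), True
    warnings.warn(
        "no threshold with sensitivity > specificity; "
        "falling back to unconstrained Youden maximum",
        stacklevel=2,
    )
    return float(thr[int(np.argmax(j))]), False


def mmse_benchmark(mmse_scores, labels, cutoffs=range(24, 29)) -> pd.DataFrame:
    """Screening metrics of raw MMSE cutoffs, the comparison standard.

    A participant screens positive (impaired) when MMSE < cutoff.  Returns
    one row per cutoff with accuracy, sensitivity and specificity.
    """
    m = np.asarray(mmse_scores)
    labels = np.asarray(labels).astype(int)
    if m.min() < 0 or m.max() > 30:
        raise EvaluationError("MMSE scores must lie in [0, 30]")
    rows = []
    for c in cutoffs:
        pred = (m < c).astype(int)
        met = metrics_from_confusion(ConfusionMatrix.from_predictions(labels, pred))
        rows.append(
            {
                "cutoff": int(c),
                "accuracy": met.accuracy,
                "sensitivity": met.sensitivity,
                "specificity": met.specificity,
            }
        )
    return pd.DataFrame(rows)
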