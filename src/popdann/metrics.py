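"""Evaluation metrics: AUPRC, MAE, RMSE, bias and Welch's t-test.

All metrics are implemented directly (step integration of the
precision-recall curve; the Welch-Satterthwaite unequal-variance t) so that
library implementations (scikit-learn, scipy) can serve as independent
cross-checks in the test-suite rather than as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "auprc",
    "mae",
    "rmse",
    "bias",
    "welch_t",
    "MetricsReport",
    "regression_report",
    "classification_report",
]


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve by step integration.

    Computed as sum_k (R_k - R_{k-1}) * P_k over score-descending thresholds
    (the average-precision form, no trapezoid interpolation). Labels must be
    binary with both classes present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or len(labels) == 0:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    pos = labels == 1
    n_pos = int(pos.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPRC undefined: labels contain a single class")
    order = np.argsort(-scores, kind="stable")
    y = pos[order].astype(float)
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # evaluate only at distinct-threshold boundaries (last index of each run)
    distinct = np.append(s[1:] != s[:-1], True)
    precision, recall = precision[distinct], recall[distinct]
    dr = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(dr * precision))


def mae(true, predicted) -> float:
    true, predicted = np.asarray(true, float), np.asarray(predicted, float)
    return float(np.mean(np.abs(predicted - true)))


def rmse(true, predicted) -> float:
    true, predicted = np.asarray(true, float), np.asarray(predicted, float)
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


def bias(true, predicted) -> float:
    """Mean signed error (predicted minus true); negative = underestimation."""
    true, predicted = np.asarray(true, float), np.asarray(predicted, float)
    return float(np.mean(predicted - true))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t: returns (t, df, p).

    df by the Welch-Satterthwaite approximation; p two-sided from the t
    distribution (scipy supplies the distribution function only).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class MetricsReport:
    """Per-scenario evaluation summary."""

    task: str
    n: int
    auprc: float | None = None
    mae: float | None = None
    rmse: float | None = None
    bias: float | None = None
    welch: tuple[float, float, float] | None = None
    predictions: np.ndarray | None = field(default=None, repr=False)
    truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.auprc is not None and not (0.0 <= self.auprc <= 1.0):
            raise ValueError("AUPRC must lie in [0, 1]")
        if (
            self.rmse is not None
            and self.bias is not None
            and self.rmse < abs(self.bias) - 1e-12
        ):
            raise ValueError("RMSE cannot be smaller than |bias|")

    def to_dict(self) -> dict:
        d = {"task": self.task, "n": self.n}
        for k in ("auprc", "mae", "rmse", "bias"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.welch is not None:
            d["welch_t"], d["welch_df"], d["welch_p"] = self.welch
        return d


def regression_report(task, true, predicted) -> MetricsReport:
    true = np.asarray(true, float)
    predicted = np.asarray(predicted, float)
    return MetricsReport(
        task=task,
        n=len(true),
        mae=mae(true, predicted),
        rmse=rmse(true, predicted),
        bias=bias(true, predicted),
        predictions=predicted,
        truth=true,
    )


def classification_report(task, labels, scores) -> MetricsReport:
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    return MetricsReport(
        task=task,
        n=len(labels),
        auprc=auprc(labels, scores),
        predictions=scores,
        truth=labels.astype(float),
    )
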