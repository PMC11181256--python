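"""Diagnostic-performance evaluation: confusion metrics, ROC/AUC with
DeLong variance, DeLong's paired AUC test, chi-square accuracy comparison,
and reader-study tables.

GISTs are the positive class throughout. AUC is computed by the
Mann-Whitney statistic (ties count 1/2), which equals the trapezoidal area
under the empirical ROC curve; its variance and 95% CI use DeLong's
structural components with a normal approximation. The paired DeLong test
compares two AUCs measured on the same lesions, accounting for their
correlation. Accuracy comparisons between the classifier and human readers
use the Pearson chi-square test on the 2x2 correct/incorrect table without
continuity correction. Displayed percentages are rounded half-up to two
decimals; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .classification import CVResult

__all__ = [
    "ConfusionCounts",
    "RocSummary",
    "ReaderResult",
    "DelongResult",
    "round_half_up",
    "confusion_metrics",
    "confusion_from_cv",
    "roc_auc",
    "delong_paired",
    "compare_accuracy_chi2",
    "reader_table",
    "plot_roc",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (decimal-exact), matching
    clinical-table display rather than banker's rounding."""
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class RocSummary:
    auc: float
    variance: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (k, 2) array of (fpr, tpr) points


@dataclass(frozen=True)
class ReaderResult:
    """A human reader's true-positive / true-negative counts against fixed
    class totals."""

    reader_id: str
    tp: int
    tn: int
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.tp <= self.n_pos and 0 <= self.tn <= self.n_neg):
            raise ValueError(f"reader {self.reader_id}: counts exceed class totals")

    def to_confusion(self) -> ConfusionCounts:
        return ConfusionCounts(
            tp=self.tp, tn=self.tn, fp=self.n_neg - self.tn, fn=self.n_pos - self.tp
        )


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent, full precision."""
    if c.n_pos < 1 or c.n_neg < 1:
        raise ValueError("both classes must be non-empty")
    return (
        100.0 * c.tp / c.n_pos,
        100.0 * c.tn / c.n_neg,
        100.0 * c.n_correct / c.total,
    )


def confusion_from_cv(result: CVResult) -> ConfusionCounts:
    t, p = result.true_labels, result.predicted_labels
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components via midranks.

    V10[k] is the placement of positive k among the negatives (fraction of
    negatives it beats, ties 1/2); V01[l] likewise for negative l. The AUC
    is the mean of either component vector.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores, method="average")
    r_pos = stats.rankdata(pos, method="average")
    r_neg = stats.rankdata(neg, method="average")
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(result: CVResult | tuple[np.ndarray, np.ndarray]) -> RocSummary:
    """ROC curve and AUC with DeLong variance and normal-theory 95% CI.

    Accepts a :class:`~eustex.classification.CVResult` (pooled LOOCV
    decision scores) or a ``(scores, labels)`` pair.
    """
    if isinstance(result, CVResult):
        scores, labels = result.scores, result.true_labels
    else:
        scores, labels = result
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    half = 1.959963984540054 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return RocSummary(auc=auc, variance=var, ci95=ci, curve=np.column_stack([fpr, tpr]))


def delong_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DelongResult:
    """DeLong's paired test for two correlated AUCs on the same lesions.

    The variance of the AUC difference comes from the covariance of the
    paired structural components; z = (auc_a - auc_b) / sd(diff), two-sided
    normal p-value. Identical AUCs with zero variance return p = 1; unequal
    AUCs with zero variance are degenerate and raise.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired design: score lists and labels must align")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        if diff == 0:
            return DelongResult(auc_a, auc_b, 0.0, 1.0)
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = diff / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(z), float(p))


def compare_accuracy_chi2(
    correct_a: int, n_a: int, correct_b: int, n_b: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2 correct/incorrect x method table.

    No Yates continuity correction by default. Returns (chi2, p). A table
    with identical proportions gives chi2 = 0, p = 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("sample sizes must be >= 1")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=np.float64
    )
    if np.any(table.sum(axis=0) == 0):
        # all correct (or all incorrect) in both groups: no association testable
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def reader_table(readers: list[ReaderResult]) -> pd.DataFrame:
    """Per-reader sensitivity/specificity/accuracy (percent) plus an
    unweighted mean row; class totals must agree across readers."""
    if not readers:
        raise ValueError("no readers")
    n_pos, n_neg = readers[0].n_pos, readers[0].n_neg
    rows = []
    for r in readers:
        if (r.n_pos, r.n_neg) != (n_pos, n_neg):
            raise ValueError(f"reader {r.reader_id}: inconsistent class totals")
        sens, spec, acc = confusion_metrics(r.to_confusion())
        rows.append(
            {
                "reader_id": r.reader_id,
                "tp": r.tp,
                "tn": r.tn,
                "sensitivity": sens,
                "specificity": spec,
                "accuracy": acc,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "reader_id": "mean",
        "tp": df["tp"].mean(),
        "tn": df["tn"].mean(),
        "sensitivity": df["sensitivity"].mean(),
        "specificity": df["specificity"].mean(),
        "accuracy": df["accuracy"].mean(),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def plot_roc(summaries: dict[str, RocSummary], path: str) -> None:
    """Save an ROC plot (one curve per feature combination) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, s in summaries.items():
        ax.plot(s.curve[:, 0], s.curve[:, 1], label=f"{name} (AUC={s.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
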