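"""Model assessment: ROC/AUC on out-of-bag scores, the threshold table,
sensitivity-specificity-sum threshold selection, the true skill statistic
(TSS), and independent testing-point validation.

Conventions
-----------
* A prediction is positive iff score >= threshold (inclusive), matching
  the binary-map rule "predicted presence iff RIO >= cut-off".
* AUC is the rank (Mann-Whitney) statistic: the probability that a random
  positive outscores a random negative, ties counted half.
* TSS = sensitivity + specificity - 1.
* The selected threshold maximizes sensitivity + specificity over the
  tabulated grid; ties break toward the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import PointTable

__all__ = [
    "ThresholdTable",
    "ValidationSummary",
    "roc_auc",
    "threshold_table",
    "select_threshold",
    "tss",
    "validate_on_test",
]


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes (labels 0 and 1) must be present")
    return pos, neg


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve via the rank formulation.

    Equals the probability that a uniformly random positive receives a
    higher score than a uniformly random negative, with ties counted half:
    AUC = (R_pos - n_pos (n_pos + 1) / 2) / (n_pos * n_neg), where R_pos is
    the sum of midranks of the positives.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = rankdata(scores, method="average")
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class ThresholdTable:
    """Per-threshold confusion summaries from scores vs labels.

    One row per threshold in {0, step, 2*step, ..., 1}; each row holds the
    sensitivity TP/(TP+FN), specificity TN/(TN+FP) and TSS obtained when
    predicting positive iff score >= threshold.
    """

    table: pd.DataFrame  # columns: threshold, sensitivity, specificity, tss

    def __len__(self) -> int:
        return len(self.table)

    def row_at(self, threshold: float) -> pd.Series:
        i = int(np.argmin(np.abs(self.table["threshold"].to_numpy() - threshold)))
        return self.table.iloc[i]


def threshold_table(labels, scores, step: float = 0.01) -> ThresholdTable:
    """Tabulate sensitivity/specificity/TSS over a regular threshold grid."""
    if not 0 < step <= 0.5:
        raise ValueError(f"step must be in (0, 0.5], got {step}")
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    n_pos, n_neg = pos.sum(), neg.sum()
    n_steps = int(round(1.0 / step))
    thresholds = np.linspace(0.0, 1.0, n_steps + 1)
    # vectorized confusion counts: predictions positive iff score >= t
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & pos[None, :]).sum(axis=1)
    tn = (~pred & neg[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    df = pd.DataFrame({
        "threshold": thresholds,
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0,
    })
    return ThresholdTable(df)


def select_threshold(table: ThresholdTable) -> float:
    """Threshold maximizing sensitivity + specificity.

    This is an exhaustive argmax over the tabulated rows; ties break toward
    the smaller threshold (np.argmax returns the first maximum and the
    table is ordered by threshold).
    """
    if len(table) == 0:
        raise ValueError("empty threshold table")
    df = table.table
    total = df["sensitivity"].to_numpy() + df["specificity"].to_numpy()
    return float(df["threshold"].to_numpy()[int(np.argmax(total))])


def tss(row) -> float:
    """True skill statistic of one threshold-table row:
    sensitivity + specificity - 1."""
    return float(row["sensitivity"] + row["specificity"] - 1.0)


@dataclass
class ValidationSummary:
    """Median test-point RIO with a percentile-bootstrap 95% CI."""

    rios: np.ndarray
    median: float
    ci_lower: float
    ci_upper: float
    n_test: int
    n_bootstrap: int = 1000


def validate_on_test(test_points: PointTable, n_bootstrap: int = 1000,
                     seed: int = 0) -> ValidationSummary:
    """Summarize scored testing points: median RIO and its bootstrap CI.

    ``test_points`` must already carry RIO scores (from scoring the model
    or extracting the prediction surface).  The CI is the 2.5/97.5
    percentile of medians over seeded bootstrap resamples.
    """
    if len(test_points) == 0:
        raise ValueError("empty test set")
    rios = np.asarray(test_points.rio, dtype=float)
    rios = rios[~np.isnan(rios)]
    if len(rios) == 0:
        raise ValueError("all test points have missing RIO")
    med = float(np.median(rios))
    rng = np.random.default_rng(seed)
    boot = np.median(
        rng.choice(rios, size=(n_bootstrap, len(rios)), replace=True), axis=1
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ValidationSummary(
        rios=rios,
        median=med,
        ci_lower=float(min(lo, med)),
        ci_upper=float(max(hi, med)),
        n_test=len(rios),
        n_bootstrap=n_bootstrap,
    )
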