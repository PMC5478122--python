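"""ROC analysis: AUC, ROC curves, DeLong paired AUC comparison, reports.

AUC is computed as the tie-corrected Mann-Whitney statistic (ties credit
1/2), which equals the trapezoidal area under the empirical ROC curve.
Paired AUC differences between two scorers evaluated on the same clips are
tested with DeLong's nonparametric method based on placement values
(structural components), with a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    present = set(np.unique(labels))
    if not present <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(present)}")
    if present != {0, 1}:
        raise ValueError("both classes must be present")
    return labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-corrected Mann-Whitney AUC of scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)  # average ranks handle ties with credit 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC curve over the distinct score thresholds (descending).

    A sample is called positive when its score is >= the threshold, so the
    curve runs from (0, 0) (threshold above every score) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n1, n0 = int(y.sum()), int((1 - y).sum())
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last index of each run of equal scores
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n1])
    fpr = np.concatenate([[0.0], fps[distinct] / n0])
    thresholds = np.concatenate([[np.inf], s[distinct]])
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area)


# ---------------------------------------------------------------------------
# DeLong


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative), plus the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(X_i, Y_j) = 1 if X > Y, 1/2 if tie, 0 otherwise
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    variance: float
    z: float
    p_value: float


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    alternative: str = "two-sided",
) -> AUCComparison:
    """DeLong test for the difference of two correlated AUCs on shared labels.

    The variance of ``auc_a - auc_b`` is estimated from the empirical
    covariance of the placement values of the two scorers.  Identical score
    vectors return p = 1 by convention; a zero variance estimate with
    unequal AUCs is an error (the asymptotic test is undefined there).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    v10a, v01a, auc_a = _placements(a, labels)
    v10b, v01b, auc_b = _placements(b, labels)
    if np.array_equal(a, b):
        return AUCComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        if auc_a == auc_b:
            return AUCComparison(auc_a, auc_b, float(max(var, 0.0)), 0.0, 1.0)
        raise ValueError("zero variance estimate with unequal AUCs; DeLong test undefined")
    z = (auc_a - auc_b) / np.sqrt(var)
    if alternative == "two-sided":
        p = 2 * norm.sf(abs(z))
    elif alternative == "greater":
        p = norm.sf(z)
    else:
        p = norm.cdf(z)
    return AUCComparison(auc_a, auc_b, float(var), float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# Reporting


def report(
    per_subject: Mapping[str, tuple[Sequence[float], Sequence[int]]],
) -> pd.DataFrame:
    """Per-subject AUC table plus a pooled row over all subjects' predictions.

    ``per_subject`` maps subject id to ``(scores, labels)``.  A subject
    whose labels are all one class gets AUC NaN; its scores still enter the
    pool (the pooled AUC is computed on the concatenation of everything).
    """
    if not per_subject:
        raise ValueError("no subjects to report")
    rows = []
    all_scores: list[float] = []
    all_labels: list[int] = []
    for subject in sorted(per_subject):
        scores, labels = per_subject[subject]
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(int)
        all_scores.extend(scores.tolist())
        all_labels.extend(labels.tolist())
        try:
            value = auc(scores, labels)
        except ValueError:
            value = np.nan
        rows.append({"subject": subject, "n": labels.size, "auc": value})
    pooled = auc(all_scores, all_labels)
    rows.append({"subject": "pool", "n": len(all_labels), "auc": pooled})
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    lines = [f"{'subject':<12} {'n':>6} {'auc':>8}"]
    for row in table.itertuples():
        auc_txt = "   undef" if pd.isna(row.auc) else f"{row.auc:8.3f}"
        lines.append(f"{row.subject:<12} {row.n:>6} {auc_txt}")
    return "\n".join(lines)
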