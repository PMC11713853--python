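"""ROI-level statistics: paired cancer-vs-normal comparison and ROC analysis.

The quantitative endpoint of the pipeline is a per-case table of ROI
summaries (lambda_r, ADC, T2 for one cancer and one normal ROI per case).
Paired differences are tested with the Wilcoxon signed-rank test; each
feature's discriminative performance is measured by the ROC AUC, which for
a finite sample equals the Mann-Whitney pair-ordering probability.  A
logistic combination of the three features gives the combined in-sample
AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocResult",
    "roi_summary",
    "wilcoxon_signed_rank",
    "roc_auc",
    "combined_auc",
    "paired_feature_table",
]


@dataclass(frozen=True)
class RocResult:
    """ROC analysis of one score against binary labels.

    ``auc`` is oriented so that it is >= 0.5; ``direction`` is +1 when
    higher scores indicate the positive class and -1 when the orientation
    was flipped.  ``fpr``/``tpr``/``thresholds`` describe the (oriented)
    operating points.
    """

    auc: float
    direction: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def roi_summary(
    values: np.ndarray,
    roi_mask: np.ndarray,
    statistic: str = "median",
    exclude_flagged: Optional[np.ndarray] = None,
) -> float:
    """Scalar ROI summary of a parameter map.

    The median (default) is robust to the heavy upper tail that capped
    lambda_r pixels would otherwise contribute; those pixels can be
    excluded outright by passing their flag map via ``exclude_flagged``.
    """
    values = np.asarray(values, dtype=float)
    sel = np.asarray(roi_mask, dtype=bool) & np.isfinite(values)
    if exclude_flagged is not None:
        sel &= ~np.asarray(exclude_flagged, dtype=bool)
    if not sel.any():
        raise ValueError("ROI contains no finite, unflagged values")
    if statistic == "median":
        return float(np.median(values[sel]))
    if statistic == "mean":
        return float(np.mean(values[sel]))
    raise ValueError(f"unknown statistic {statistic!r}")


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]):
    """Two-sided Wilcoxon signed-rank test on per-case (cancer, normal)
    value pairs.

    Zero differences are dropped (Wilcoxon's original treatment) and tied
    absolute differences receive midranks.  The exact null distribution is
    used for n <= 25 when there are no ties; otherwise the normal
    approximation with tie correction.  Returns ``(W, p)`` where W is the
    smaller of the positive/negative rank sums.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (cancer, normal) tuples")
    diff = arr[:, 0] - arr[:, 1]
    diff = diff[diff != 0.0]
    if diff.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    has_ties = len(np.unique(np.abs(diff))) < len(diff)
    method = "exact" if (len(diff) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(diff, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores, labels) -> RocResult:
    """ROC AUC of a score for binary labels (1 = cancer/positive).

    Ties contribute 1/2 per pair, so the AUC equals the Mann-Whitney
    U statistic scaled by n_pos * n_neg.  Scores that rank the negative
    class higher are flipped and reported with ``direction = -1``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    auc = float(roc_auc_score(labels, scores))
    direction = 1
    oriented = scores
    if auc < 0.5:
        auc, direction, oriented = 1.0 - auc, -1, -scores
    fpr, tpr, thr = roc_curve(labels, oriented)
    return RocResult(auc, direction, fpr, tpr, thr, n_pos, n_neg)


def combined_auc(
    features: np.ndarray,
    labels,
    feature_names: Optional[Sequence[str]] = None,
) -> tuple[RocResult, np.ndarray]:
    """In-sample AUC of a logistic combination of several features.

    Features are standardized and combined by (near-unpenalized) logistic
    regression; the fitted linear score is evaluated in-sample, matching a
    small-cohort setting where no held-out data exist.  Constant features
    are dropped with a warning.  If the logistic score happens to rank
    cases worse than the best single feature, that feature's score is used
    instead, so the combination never loses to its own inputs in-sample.

    Returns ``(RocResult, combined_scores)``.
    """
    y = np.asarray(labels).astype(int)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("feature matrix does not match number of labels")
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if len(keep) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        names = (
            [feature_names[j] for j in dropped] if feature_names else dropped
        )
        warnings.warn(f"dropping constant feature(s) {names}", stacklevel=2)
    if not keep:
        raise ValueError("all features are constant; nothing to combine")
    Xk = X[:, keep]
    mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
    Z = (Xk - mu) / sd
    model = LogisticRegression(C=1e6, max_iter=10_000)
    model.fit(Z, y)
    score = Z @ model.coef_.ravel()
    singles = [(roc_auc(X[:, j], y), j) for j in keep]
    best_single, best_j = max(singles, key=lambda t: t[0].auc)
    combined = roc_auc(score, y)
    if combined.auc < best_single.auc:
        combined = best_single
        score = best_single.direction * X[:, best_j]
    return combined, score


def paired_feature_table(
    cancer: dict[str, Sequence[float]], normal: dict[str, Sequence[float]]
) -> pd.DataFrame:
    """Long-to-wide helper: build a per-case table with one row per case
    and ``<feature>_cancer`` / ``<feature>_normal`` columns."""
    if set(cancer) != set(normal):
        raise ValueError("cancer and normal tables list different features")
    data = {}
    n = None
    for feat in cancer:
        c, m = np.asarray(cancer[feat], float), np.asarray(normal[feat], float)
        if len(c) != len(m):
            raise ValueError(f"feature {feat!r} has unequal case counts")
        if n is None:
            n = len(c)
        elif len(c) != n:
            raise ValueError("features have inconsistent case counts")
        data[f"{feat}_cancer"] = c
        data[f"{feat}_normal"] = m
    return pd.DataFrame(data)
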