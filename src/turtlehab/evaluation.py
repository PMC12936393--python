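"""Shared model-performance metrics.

AUC is the rank-based (Mann-Whitney) statistic with midrank tie handling;
TSS (true skill statistic) is sensitivity + specificity - 1 at a
classification threshold (default 0.5, i.e. "presence more likely than
not"), with the maximum-TSS threshold reported as a secondary value; percent
deviance explained is (null deviance - residual deviance) / null deviance
under the Bernoulli likelihood, the null model being the evaluation set's
own label mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetricReport", "auc", "tss_tpr", "deviance_explained", "metric_report"]

_CLIP = 1e-12


def _check(labels, scores):
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    return y, s


def auc(labels, scores) -> float:
    """Area under the ROC curve, computed from midranks.

    Equals the probability that a random presence outscores a random absence,
    counting ties as half. Errors when only one class is present.
    """
    y, s = _check(labels, scores)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def tss_tpr(labels, scores, threshold: float = 0.5) -> tuple[float, float]:
    """(TSS, TPR) at a threshold; predicted positive iff score > threshold."""
    y, s = _check(labels, scores)
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise ValueError("TSS undefined with a single class")
    pred = s > threshold
    tpr = float((pred & pos).sum() / pos.sum())
    tnr = float((~pred & neg).sum() / neg.sum())
    return tpr + tnr - 1.0, tpr


def max_tss(labels, scores) -> tuple[float, float]:
    """Maximum TSS over every distinct score threshold; returns (tss, threshold)."""
    y, s = _check(labels, scores)
    sp = np.sort(s[y == 1])
    sn = np.sort(s[y == 0])
    if len(sp) == 0 or len(sn) == 0:
        raise ValueError("TSS undefined with a single class")
    # candidate thresholds: every distinct score, plus one below the minimum
    # (everything predicted positive)
    cand = np.concatenate([[s.min() - 1e-9], np.unique(s)])
    tpr = 1.0 - np.searchsorted(sp, cand, side="right") / len(sp)
    tnr = np.searchsorted(sn, cand, side="right") / len(sn)
    tss = tpr + tnr - 1.0
    i = int(np.argmax(tss))
    return float(tss[i]), float(cand[i])


def deviance_explained(labels, scores) -> float:
    """Percent deviance explained under the Bernoulli likelihood.

    D(p) = -2 sum[y ln p + (1-y) ln(1-p)]; the null model predicts the
    evaluation set's label mean everywhere. Scores exactly 0 or 1 are clipped
    with a warning.
    """
    y, s = _check(labels, scores)
    if ((s <= 0) | (s >= 1)).any():
        warnings.warn("scores at 0 or 1 clipped for the deviance computation")
    p = np.clip(s, _CLIP, 1.0 - _CLIP)
    ybar = np.clip(y.mean(), _CLIP, 1.0 - _CLIP)
    d_model = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    d_null = -2.0 * np.sum(y * np.log(ybar) + (1 - y) * np.log(1 - ybar))
    return float((d_null - d_model) / d_null)


@dataclass
class MetricReport:
    """Headline metrics at one threshold, plus the max-TSS secondary values."""

    auc: float
    tss: float
    tpr: float
    deviance_explained: float
    threshold: float = 0.5
    tss_max: float = np.nan
    tss_max_threshold: float = np.nan
    per_fold: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"auc": self.auc, "tss": self.tss, "tpr": self.tpr,
                "deviance_explained": self.deviance_explained,
                "threshold": self.threshold, "tss_max": self.tss_max,
                "tss_max_threshold": self.tss_max_threshold}


def metric_report(labels, scores, threshold: float = 0.5) -> MetricReport:
    """All metrics on one evaluation set (held-out rows)."""
    tss, tpr = tss_tpr(labels, scores, threshold)
    tmax, tthr = max_tss(labels, scores)
    return MetricReport(
        auc=auc(labels, scores), tss=tss, tpr=tpr,
        deviance_explained=deviance_explained(labels, scores),
        threshold=threshold, tss_max=tmax, tss_max_threshold=tthr)
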