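"""Validation statistics: ROC, operating points, Kaplan-Meier, log-rank.

ROC AUC is computed as Mann-Whitney pairwise concordance (ties credited
0.5), which equals the trapezoid area under the empirical ROC curve.
Recurrence-free survival uses the product-limit (Kaplan-Meier) estimator
and the standard one-degree-of-freedom log-rank test with an asymptotic
chi-square p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats


@dataclass(frozen=True)
class ROCResult:
    auc: float
    #: (threshold, sensitivity, specificity) per candidate cutoff,
    #: thresholds descending; positive call is score > threshold.
    operating_points: tuple[tuple[float, float, float], ...]


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); steps drop at event times (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) == {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    return y


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC with Mann-Whitney AUC.

    AUC = mean over all (positive, negative) pairs of 1[s+ > s-] + 0.5*1[tie],
    i.e. the probability a recurrent patient outscores a non-recurrent one.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    # midrank formulation: sum of positive ranks counts wins + half-ties
    ranks = _stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    points = []
    for thr in np.unique(s)[::-1]:
        sens, spec = sensitivity_specificity(s, y, float(thr))
        points.append((float(thr), sens, spec))
    return ROCResult(auc=float(auc), operating_points=tuple(points))


def sensitivity_specificity(scores, labels, cutoff: float) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with positive call = score > cutoff."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate for one group.

    ``events`` is 1 for an observed event (recurrence) at ``times``, 0 for
    right-censoring.  At each distinct event time t with d events among n
    at risk, S multiplies by (1 - d/n); censored subjects leave the risk
    set after their censoring time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.shape != e.shape or t.size == 0:
        raise ValueError("times and events must align and be non-empty")
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
    )


def one_year_rfs(times, events, horizon_days: float = 365.0) -> float:
    """Kaplan-Meier S(365): fraction recurrence-free at one year."""
    return km_estimate(times, events).survival_at(horizon_days)


def log_rank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test (1 d.f., asymptotic chi-square p-value).

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk sets;
    chi2 = (sum(O-E))^2 / sum(V).
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t_all[e_all == 1]):
        at_risk = t_all >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & (grp == 0)).sum())
        d = int(((t_all == et) & (e_all == 1)).sum())
        d_a = int(((t_all == et) & (e_all == 1) & (grp == 0)).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(chi_square=0.0, p_value=1.0)
    chi2 = o_minus_e**2 / var
    return LogRankResult(chi_square=float(chi2), p_value=float(_stats.chi2.sf(chi2, df=1)))


def orient_scores(scores, labels) -> tuple[np.ndarray, int]:
    """Flip score sign if needed so AUC >= 0.5; returns (scores, sign).

    Used for covariates whose risk direction is a convention (e.g. HPV
    status, where HPV-negative is the risk-increasing direction).
    """
    s = np.asarray(scores, dtype=float)
    if roc_auc(s, labels).auc >= 0.5:
        return s, 1
    return -s, -1
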