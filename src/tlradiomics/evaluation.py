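"""Diagnostic-model evaluation statistics.

ROC/AUC with DeLong machinery (structural components), threshold metrics
at a Youden-index operating point, integrated discrimination improvement
(IDI), Hosmer-Lemeshow calibration, decision-curve analysis and
stratified analysis.  Conventions: the positive class is label 1 (LAC);
a sample is called positive when its score is >= the threshold; all
tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .errors import DataError, ParameterError

__all__ = [
    "EvalReport",
    "auc",
    "delong_variance",
    "delong_test",
    "delong_ci",
    "confusion_at",
    "youden_threshold",
    "idi",
    "hosmer_lemeshow",
    "decision_curve",
    "stratified_analysis",
]


def _validate(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise DataError("scores and labels must be 1-D and of equal length")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or len(classes) != 2:
        raise DataError("labels must contain both classes 0 and 1")
    return s, y.astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    s, y = _validate(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _structural_components(scores, labels):
    """DeLong V10 (per case) and V01 (per control) components."""
    s, y = _validate(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp_mat.mean(axis=1)
    v01 = cmp_mat.mean(axis=0)
    return v10, v01, float(cmp_mat.mean())


def _var1(v):
    return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    v10, v01, _ = _structural_components(scores, labels)
    return float(_var1(v10) / len(v10) + _var1(v01) / len(v01))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """(AUC, lower, upper): normal CI with DeLong SE, truncated to [0, 1]."""
    a = auc(scores, labels)
    se = np.sqrt(max(delong_variance(scores, labels), 0.0))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return a, float(max(0.0, a - zq * se)), float(min(1.0, a + zq * se))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for two correlated AUCs on the same patients.

    Returns (z, p).  Degenerate (zero-variance) differences — e.g.
    identical score vectors — give (0, 1).
    """
    sa, y = _validate(scores_a, labels)
    sb, _ = _validate(scores_b, labels)
    v10a, v01a, auc_a = _structural_components(sa, y)
    v10b, v01b, auc_b = _structural_components(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var <= 1e-16:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class EvalReport:
    """Threshold metrics with their numerator/denominator counts."""

    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    cohort: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_at(scores, labels, threshold: float, cohort: str = "") -> EvalReport:
    """Sens/spec/acc/PPV/NPV at ``score >= threshold`` -> positive."""
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    s, y = _validate(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    a, lo, hi = delong_ci(s, y)

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return EvalReport(
        auc=a, ci_low=lo, ci_high=hi, threshold=float(threshold),
        sensitivity=_ratio(tp, tp + fn), specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, len(y)), ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn), tp=tp, fp=fp, tn=tn, fn=fn, cohort=cohort,
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity - 1; ties -> lowest."""
    s, y = _validate(scores, labels)
    candidates = np.unique(s)
    best_t, best_j = candidates[0], -np.inf
    n1 = y.sum()
    n0 = len(y) - n1
    for t in candidates:
        pred = s >= t
        sens = np.sum(pred & (y == 1)) / n1
        spec = np.sum(~pred & (y == 0)) / n0
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def idi(p_old, p_new, labels) -> tuple[float, float]:
    """Integrated discrimination improvement and its paired z-test p-value.

    IDI = (mean p_new | cases - mean p_new | controls)
        - (mean p_old | cases - mean p_old | controls).
    """
    po, y = _validate(p_old, labels)
    pn, _ = _validate(p_new, labels)
    d = pn - po
    d_case = d[y == 1]
    d_ctrl = d[y == 0]
    idi_val = float(d_case.mean() - d_ctrl.mean())
    se = np.sqrt(
        np.var(d_case, ddof=1) / len(d_case) + np.var(d_ctrl, ddof=1) / len(d_ctrl)
    )
    if se <= 1e-16:
        return idi_val, 1.0
    z = idi_val / se
    return idi_val, float(2 * stats.norm.sf(abs(z)))


def hosmer_lemeshow(probs, labels, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit over ``g`` equal-count risk groups.

    Samples are ordered by predicted risk; tied predictions go to the
    lower group.  chi2 = sum (O - E)^2 / (E (1 - E/n_g)); df = g - 2.
    Groups emptied by tie handling are merged with a warning.
    """
    p, y = _validate(probs, labels)
    n = len(p)
    if n < 2 * g:
        raise DataError(f"need at least 2g = {2 * g} samples")
    order = np.argsort(p, kind="mergesort")
    group = np.empty(n, dtype=int)
    base = (np.arange(n) * g) // n
    # ties to lower group: equal probs share the group of their first occurrence
    sorted_p = p[order]
    for i in range(1, n):
        if sorted_p[i] == sorted_p[i - 1]:
            base[i] = base[i - 1]
    group[order] = base

    chi2 = 0.0
    used = 0
    for k in np.unique(group):
        mask = group == k
        ng = mask.sum()
        if ng == 0:
            continue
        obs = y[mask].sum()
        exp = p[mask].sum()
        denom = exp * (1.0 - exp / ng)
        if denom <= 1e-12:
            denom = 1e-12
        chi2 += (obs - exp) ** 2 / denom
        used += 1
    if used < g:
        warnings.warn(f"tie handling merged groups: {used} of {g} used", RuntimeWarning)
    df = max(used - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df))


def decision_curve(
    probs, labels, thresholds=None
) -> pd.DataFrame:
    """Net benefit of the model, treat-all and treat-none per threshold pt.

    NB(pt) = TP/n - FP/n * pt/(1-pt); treat-none is identically zero;
    pt = 1 has an undefined weight and is reported as NaN.
    """
    p, y = _validate(probs, labels)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0001, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ParameterError("threshold grid is empty")
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        if pt >= 1.0:
            rows.append(dict(threshold=pt, net_benefit_model=np.nan,
                             net_benefit_all=np.nan, net_benefit_none=0.0))
            continue
        w = pt / (1.0 - pt)
        pred = p >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        rows.append(
            dict(
                threshold=pt,
                net_benefit_model=tp - fp * w,
                net_benefit_all=prevalence - (1 - prevalence) * w,
                net_benefit_none=0.0,
            )
        )
    return pd.DataFrame(rows)


def stratified_analysis(scores, labels, strata) -> pd.DataFrame:
    """Per-stratum AUC with a DeLong comparison against the pooled cohort.

    The pooled-vs-stratum covariance is estimated from the structural
    components of the shared (stratum) samples; single-class strata are
    skipped with a flag.  A stratum equal to the full cohort compares a
    quantity with itself and reports p = 1.
    """
    s, y = _validate(scores, labels)
    strata = np.asarray(strata)
    if strata.shape != y.shape:
        raise DataError("strata must align with labels")
    auc_pool = auc(s, y)
    v10p, v01p, _ = _structural_components(s, y)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    pos_lookup = {idx: k for k, idx in enumerate(pos_idx)}
    neg_lookup = {idx: k for k, idx in enumerate(neg_idx)}

    rows = []
    for level in pd.unique(strata):
        mask = strata == level
        ys = y[mask]
        if len(np.unique(ys)) < 2 or mask.sum() < 4:
            rows.append(dict(stratum=level, n=int(mask.sum()), auc=np.nan,
                             ci_low=np.nan, ci_high=np.nan, delong_p=np.nan,
                             skipped=True))
            warnings.warn(f"stratum {level!r} skipped (single class or too small)",
                          RuntimeWarning)
            continue
        ss = s[mask]
        a, lo, hi = delong_ci(ss, ys)
        v10s, v01s, _ = _structural_components(ss, ys)
        m_s, n_s = len(v10s), len(v01s)
        m_p, n_p = len(v10p), len(v01p)
        idx = np.flatnonzero(mask)
        pos_shared = [pos_lookup[i] for i in idx if y[i] == 1]
        neg_shared = [neg_lookup[i] for i in idx if y[i] == 0]
        var_s = _var1(v10s) / m_s + _var1(v01s) / n_s
        var_p = _var1(v10p) / m_p + _var1(v01p) / n_p
        cov = 0.0
        if m_s > 1:
            cov += np.cov(v10s, v10p[pos_shared], ddof=1)[0, 1] * (m_s / m_p) / m_s
        if n_s > 1:
            cov += np.cov(v01s, v01p[neg_shared], ddof=1)[0, 1] * (n_s / n_p) / n_s
        var = var_s + var_p - 2 * cov
        if var <= 1e-16:
            p_val = 1.0
        else:
            z = (a - auc_pool) / np.sqrt(var)
            p_val = float(2 * stats.norm.sf(abs(z)))
        rows.append(dict(stratum=level, n=int(mask.sum()), auc=a, ci_low=lo,
                         ci_high=hi, delong_p=p_val, skipped=False))
    return pd.DataFrame(rows)
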