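"""Score evaluation: c-statistics with DeLong variance, paired DeLong tests,
per-cutoff diagnostic accuracy with CIs, score-transition tabulation and the
added-capture statistic.

The c-statistic is the Mann-Whitney pair probability (ties counted 1/2); its
variance and the paired comparison of two correlated c-statistics use
DeLong's structural-components method.  Proportion CIs default to the Wilson
score interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, DegenerateInputError
from .qsofa import CutoffRule, classify

__all__ = [
    "AucEstimate", "AccuracyMetrics", "AccuracyTable", "TransitionTable",
    "roc_auc", "delong_test", "accuracy_at_cutoff", "accuracy_table",
    "transition_table", "added_capture", "roc_coordinates",
]


# ---------------------------------------------------------------------------
# DeLong structural components


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (ties averaged), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUCs and the DeLong covariance matrix for k scores on the same patients.

    ``scores`` has shape (k, n).  Returns (aucs shape (k,), cov shape (k, k));
    covariance entries are NaN when either class has fewer than two members.
    """
    labels = np.asarray(labels, dtype=bool)
    m = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if m == 0 or n_ctrl == 0:
        raise DegenerateInputError("need at least one case and one control")
    order = np.argsort(~labels, kind="stable")  # cases first
    scores = np.asarray(scores, dtype=float)[:, order]
    k = scores.shape[0]
    v_case = np.empty((k, m))
    v_ctrl = np.empty((k, n_ctrl))
    aucs = np.empty(k)
    for r in range(k):
        x, y = scores[r, :m], scores[r, m:]
        tx, ty, tz = _midrank(x), _midrank(y), _midrank(scores[r])
        aucs[r] = tz[:m].sum() / (m * n_ctrl) - (m + 1.0) / (2.0 * n_ctrl)
        v_case[r] = (tz[:m] - tx) / n_ctrl          # structural components (cases)
        v_ctrl[r] = 1.0 - (tz[m:] - ty) / m         # structural components (controls)
    if m < 2 or n_ctrl < 2:
        cov = np.full((k, k), np.nan)
    else:
        cov = np.cov(v_case, ddof=1) / m + np.cov(v_ctrl, ddof=1) / n_ctrl
        cov = np.atleast_2d(cov)
    return aucs, cov


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    variance: float
    ci95: tuple[float, float]

    def __str__(self) -> str:
        return f"{self.auc:.2f} ({self.ci95[0]:.2f}-{self.ci95[1]:.2f})"


def roc_auc(scores, labels, logit_ci: bool = False) -> AucEstimate:
    """c-statistic with DeLong variance and 95% CI.

    The point estimate equals the Mann-Whitney pair statistic with ties
    counted one half.  The CI is the normal approximation
    ``auc +/- 1.96 sqrt(var)`` clipped to [0, 1], or, with ``logit_ci``, the
    delta-method interval on the log-odds scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have the same length")
    aucs, cov = _delong_components(scores[None, :], labels)
    auc, var = float(aucs[0]), float(cov[0, 0])
    se = np.sqrt(var) if np.isfinite(var) else np.nan
    z = stats.norm.ppf(0.975)
    if logit_ci and 0 < auc < 1 and np.isfinite(se) and se > 0:
        logit = np.log(auc / (1 - auc))
        se_l = se / (auc * (1 - auc))
        lo, hi = logit - z * se_l, logit + z * se_l
        ci = (float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi))))
    else:
        ci = (
            float(np.clip(auc - z * se, 0, 1)) if np.isfinite(se) else np.nan,
            float(np.clip(auc + z * se, 0, 1)) if np.isfinite(se) else np.nan,
        )
    return AucEstimate(auc=auc, variance=var, ci95=ci)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test of two correlated AUCs; returns (z, two-sided p).

    Antisymmetric in (a, b).  Identical scores (zero variance of the
    difference) are reported as z = 0, p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise DataError("scores_a, scores_b and labels must have equal length")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise DegenerateInputError("need at least two cases and two controls")
    aucs, cov = _delong_components(np.vstack([a, b]), labels)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        if aucs[0] != aucs[1]:
            warnings.warn("zero DeLong variance of the AUC difference; p set to 1")
        return 0.0, 1.0
    z = float((aucs[0] - aucs[1]) / np.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, max(min(p, 1.0), np.finfo(float).tiny)


def roc_coordinates(scores, labels) -> pd.DataFrame:
    """ROC curve over all observed thresholds (for plotting/export)."""
    fpr, tpr, thr = _sk_roc_curve(np.asarray(labels, dtype=int), np.asarray(scores))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# per-cutoff accuracy


def _prop_ci(k: int, n: int, method: str) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    meth = {"wilson": "wilson", "exact": "beta", "wald": "normal"}[method]
    lo, hi = proportion_confint(k, n, alpha=0.05, method=meth)
    return (float(lo), float(hi))


@dataclass(frozen=True)
class AccuracyMetrics:
    cutoff: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float                      # NaN when undefined (no test-positives)
    npv: float                      # NaN when undefined (no test-negatives)
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    undefined: tuple[str, ...] = ()


def accuracy_at_cutoff(
    scores, labels, rule: CutoffRule, ci_method: str = "wilson"
) -> AccuracyMetrics:
    """2x2 accuracy of the positivity rule ``score >= cutoff``.

    PPV/NPV are flagged undefined (NaN, name recorded) when there are no
    test-positives/-negatives rather than reported as 0.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise DegenerateInputError("need at least one case and one control")
    pos = classify(scores, rule)
    tp = int((pos & labels).sum())
    fp = int((pos & ~labels).sum())
    fn = int((~pos & labels).sum())
    tn = int((~pos & ~labels).sum())
    undefined = []
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        ppv, ppv_ci = np.nan, (np.nan, np.nan)
        undefined.append("ppv")
    else:
        ppv, ppv_ci = tp / (tp + fp), _prop_ci(tp, tp + fp, ci_method)
    if tn + fn == 0:
        npv, npv_ci = np.nan, (np.nan, np.nan)
        undefined.append("npv")
    else:
        npv, npv_ci = tn / (tn + fn), _prop_ci(tn, tn + fn, ci_method)
    return AccuracyMetrics(
        cutoff=rule.cutoff, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=_prop_ci(tp, tp + fn, ci_method),
        specificity_ci=_prop_ci(tn, tn + fp, ci_method),
        ppv_ci=ppv_ci, npv_ci=npv_ci, undefined=tuple(undefined),
    )


@dataclass
class AccuracyTable:
    score_name: str
    outcome: str
    auc: AucEstimate
    delong_p: float | None          # vs the reference score; None for the reference
    rows: list[AccuracyMetrics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        def fmt(v, ci):
            return f"{v:.2f} ({ci[0]:.2f}-{ci[1]:.2f})" if np.isfinite(v) else "undefined"

        recs = []
        for i, r in enumerate(self.rows):
            recs.append({
                "score": self.score_name,
                "outcome": self.outcome,
                "cutoff": f">= {r.cutoff}",
                "c_statistic": str(self.auc) if i == 0 else "",
                "delong_p": (
                    ("-" if self.delong_p is None else f"{self.delong_p:.2g}")
                    if i == 0 else ""
                ),
                "sensitivity": fmt(r.sensitivity, r.sensitivity_ci),
                "specificity": fmt(r.specificity, r.specificity_ci),
                "ppv": fmt(r.ppv, r.ppv_ci),
                "npv": fmt(r.npv, r.npv_ci),
            })
        if not recs:
            recs.append({
                "score": self.score_name, "outcome": self.outcome, "cutoff": "",
                "c_statistic": str(self.auc),
                "delong_p": "-" if self.delong_p is None else f"{self.delong_p:.2g}",
                "sensitivity": "", "specificity": "", "ppv": "", "npv": "",
            })
        return pd.DataFrame(recs)

    def to_long_frame(self) -> pd.DataFrame:
        recs = [{
            "score": self.score_name, "outcome": self.outcome, "cutoff": r.cutoff,
            "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "ppv": r.ppv, "npv": r.npv,
            "auc": self.auc.auc, "auc_lo": self.auc.ci95[0], "auc_hi": self.auc.ci95[1],
            "delong_p": np.nan if self.delong_p is None else self.delong_p,
        } for r in self.rows]
        return pd.DataFrame(recs)


def accuracy_table(
    cohort: pd.DataFrame,
    score_name: str,
    outcome_name: str,
    cutoffs,
    reference_score: str = "qsofa_ed",
    ci_method: str = "wilson",
) -> AccuracyTable:
    """One evaluated score against one outcome: AUC, DeLong p vs the
    reference score (ED qSOFA by default), and a row per cutoff."""
    scores = cohort[score_name].to_numpy()
    labels = cohort[outcome_name].to_numpy().astype(bool)
    auc = roc_auc(scores, labels)
    if score_name == reference_score or reference_score not in cohort.columns:
        p = None
    else:
        _, p = delong_test(scores, cohort[reference_score].to_numpy(), labels)
    rows = [
        accuracy_at_cutoff(scores, labels, CutoffRule(score_name, c), ci_method)
        for c in cutoffs
    ]
    return AccuracyTable(
        score_name=score_name, outcome=outcome_name, auc=auc, delong_p=p, rows=rows
    )


# ---------------------------------------------------------------------------
# score transitions and added capture


@dataclass
class TransitionTable:
    """Counts over (prehospital score 0-3) x (ED score 0-3) x outcome."""

    outcome: str
    counts: np.ndarray  # shape (4, 4, 2); last axis: outcome False, True

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"qsofa_pre": a, "qsofa_ed": b, "outcome": bool(o),
             "count": int(self.counts[a, b, o])}
            for a in range(4) for b in range(4) for o in range(2)
        ]
        return pd.DataFrame(recs)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def transition_table(cohort: pd.DataFrame, outcome_name: str) -> TransitionTable:
    """Tabulate prehospital-to-ED score transitions split by outcome.

    Marginals over the ED axis and outcome reproduce the prehospital score
    distribution (and vice versa).
    """
    counts = np.zeros((4, 4, 2), dtype=int)
    pre = cohort["qsofa_pre"].to_numpy().astype(int)
    ed = cohort["qsofa_ed"].to_numpy().astype(int)
    out = cohort[outcome_name].to_numpy().astype(bool)
    if ((pre < 0) | (pre > 3) | (ed < 0) | (ed > 3)).any():
        raise DataError("stage qSOFA totals must be in [0, 3]")
    np.add.at(counts, (pre, ed, out.astype(int)), 1)
    return TransitionTable(outcome=outcome_name, counts=counts)


def added_capture(
    cohort: pd.DataFrame,
    outcome_name: str,
    ed_rule: CutoffRule | None = None,
    combined_rule: CutoffRule | None = None,
) -> tuple[int, float]:
    """Outcome-positive patients flagged by the combined score but missed by
    ED qSOFA alone: combined >= cutoff AND ED < cutoff.

    Returns (count, fraction of outcome-positive patients); the fraction is
    NaN when there are no outcome-positive patients.
    """
    ed_rule = ed_rule or CutoffRule("qsofa_ed", 2)
    combined_rule = combined_rule or CutoffRule("qsofa_combined", 3)
    pos = cohort[outcome_name].to_numpy().astype(bool)
    ed_neg = ~classify(cohort["qsofa_ed"].to_numpy(), ed_rule)
    comb_pos = classify(cohort["qsofa_combined"].to_numpy(), combined_rule)
    count = int((pos & ed_neg & comb_pos).sum())
    n_pos = int(pos.sum())
    if n_pos == 0:
        warnings.warn("no outcome-positive patients; added-capture fraction undefined")
        return count, float("nan")
    return count, count / n_pos
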