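"""qSOFA scoring: per-stage component indicators, totals, and the combined score.

qSOFA awards one point each for hypotension (sBP <= 100 mmHg), tachypnoea
(RR >= 22 /min) and altered mental status (GCS <= 14).  The combined score is
the sum of the prehospital and ED totals (0-6), screened at a cutoff of >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    QSOFA_GCS_MAX,
    QSOFA_RR_MIN,
    QSOFA_SBP_MAX,
    SCORE_CUTOFFS,
    STAGES,
)
from .errors import DataError, PreconditionError

__all__ = [
    "QsofaScore", "CombinedScore", "CutoffRule",
    "score_qsofa", "combine", "classify", "score_cohort",
]


@dataclass(frozen=True)
class QsofaScore:
    stage: str
    hypotension: bool
    tachypnea: bool
    ams: bool

    @property
    def total(self) -> int:
        return int(self.hypotension) + int(self.tachypnea) + int(self.ams)


@dataclass(frozen=True)
class CombinedScore:
    prehospital_total: int
    ed_total: int

    @property
    def combined(self) -> int:
        return self.prehospital_total + self.ed_total


@dataclass(frozen=True)
class CutoffRule:
    """Positivity rule: score >= cutoff for the named score."""

    score_name: str
    cutoff: int

    def __post_init__(self) -> None:
        grid = SCORE_CUTOFFS.get(self.score_name)
        if grid is not None and self.cutoff not in grid:
            raise DataError(
                f"cutoff {self.cutoff} not admissible for {self.score_name} "
                f"(allowed: {grid})"
            )


def score_qsofa(
    sbp: float,
    rr: float,
    gcs: float,
    stage: str = "ed",
    *,
    sbp_max: float = QSOFA_SBP_MAX,
    rr_min: float = QSOFA_RR_MIN,
    gcs_max: float = QSOFA_GCS_MAX,
) -> QsofaScore:
    """Score one stage's (fully imputed) vitals.

    Raises :class:`PreconditionError` naming the field if a required vital is
    null — scoring happens after imputation, so nulls indicate a pipeline bug.
    """
    if stage not in STAGES:
        raise DataError(f"unknown stage {stage!r} (expected one of {STAGES})")
    for name, v in (("sbp", sbp), ("rr", rr), ("gcs", gcs)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise PreconditionError(f"{name} is null at stage {stage!r}; impute first")
    return QsofaScore(
        stage=stage,
        hypotension=bool(sbp <= sbp_max),
        tachypnea=bool(rr >= rr_min),
        ams=bool(gcs <= gcs_max),
    )


def combine(pre: QsofaScore, ed: QsofaScore) -> CombinedScore:
    """Sum of prehospital and ED qSOFA (range 0-6)."""
    return CombinedScore(prehospital_total=pre.total, ed_total=ed.total)


def classify(score: int | np.ndarray, rule: CutoffRule):
    """True iff score >= rule.cutoff; validates the admissible range."""
    hi = 6 if rule.score_name == "qsofa_combined" else 3
    arr = np.asarray(score)
    if ((arr < 0) | (arr > hi)).any():
        raise DataError(f"score out of range [0, {hi}] for {rule.score_name}")
    out = arr >= rule.cutoff
    return bool(out) if np.isscalar(score) or arr.ndim == 0 else out


def score_cohort(
    cohort: pd.DataFrame,
    *,
    sbp_max: float = QSOFA_SBP_MAX,
    rr_min: float = QSOFA_RR_MIN,
    gcs_max: float = QSOFA_GCS_MAX,
    from_true: bool = False,
) -> pd.DataFrame:
    """Add component booleans and `qsofa_pre`, `qsofa_ed`, `qsofa_combined`.

    With ``from_true`` the scorer reads the simulator's ground-truth
    (``*_true``) vitals instead of the observed/imputed columns.
    """
    suffix = "_true" if from_true else ""
    out = cohort.copy()
    for stage in STAGES:
        cols = [f"{v}_{stage}{suffix}" for v in ("sbp", "rr", "gcs")]
        for c in cols:
            if out[c].isna().any():
                raise PreconditionError(
                    f"column {c!r} has nulls; run the imputer before scoring"
                )
        out[f"hypotension_{stage}"] = out[cols[0]] <= sbp_max
        out[f"tachypnea_{stage}"] = out[cols[1]] >= rr_min
        out[f"ams_{stage}"] = out[cols[2]] <= gcs_max
        out[f"qsofa_{stage}"] = (
            out[f"hypotension_{stage}"].astype(int)
            + out[f"tachypnea_{stage}"].astype(int)
            + out[f"ams_{stage}"].astype(int)
        )
    out["qsofa_combined"] = out["qsofa_pre"] + out["qsofa_ed"]
    return out
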