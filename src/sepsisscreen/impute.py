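"""Iterated random-forest imputation of missing vital signs (missForest-style).

Mirrors the pipeline's imputation step: each vital column with missing values
gets a random-forest regressor trained on the remaining predictors (age, sex,
all fourteen stage-vitals, oxygen therapy and — by default, matching the
analysis this package reproduces — the outcome labels), iterating until the
normalised change between successive imputations stops decreasing.  GCS is
imputed on its ordinal scale, then rounded and clipped to [3, 15]; altered
mental status is derived downstream as GCS <= 14.

Observed cells are never modified, and tree-ensemble predictions are convex
combinations of observed values, so continuous imputations always lie within
the observed range of their column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import STAGES, VITALS, ImputationSpec, spawn_seeds
from .errors import DataError, UnimputableColumnError

__all__ = ["fit_impute", "multiple_impute", "VITAL_COLS"]

VITAL_COLS = tuple(f"{v}_{s}" for v in VITALS for s in STAGES)
BASE_PREDICTORS = ("age", "male", "oxygen_therapy")
OUTCOME_PREDICTORS = ("sepsis", "septic_shock", "in_hospital_mortality")


def _predictor_frame(df: pd.DataFrame, spec: ImputationSpec) -> list[str]:
    cols = [c for c in BASE_PREDICTORS if c in df.columns]
    cols += [c for c in VITAL_COLS if c in df.columns]
    if spec.include_outcomes_as_predictors:
        cols += [c for c in OUTCOME_PREDICTORS if c in df.columns]
    return cols


def fit_impute(
    cohort: pd.DataFrame,
    spec: ImputationSpec | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Return (completed cohort, diagnostics).

    The completed cohort has no nulls in the seven vitals at either stage;
    observed values are bitwise unchanged.  Deterministic for a given spec
    seed.  Diagnostics report per-column imputed counts and the iteration
    trajectory of the normalised change.
    """
    spec = spec or ImputationSpec()
    out = cohort.copy()
    vital_cols = [c for c in VITAL_COLS if c in out.columns]
    for c in vital_cols:
        if not pd.api.types.is_numeric_dtype(out[c]):
            raise DataError(f"vital column {c!r} is not numeric")
        if out[c].notna().sum() == 0:
            raise UnimputableColumnError(f"column {c!r} has no observed values")

    miss_mask = {c: out[c].isna().to_numpy() for c in vital_cols}
    to_impute = [c for c in vital_cols if miss_mask[c].any()]
    diagnostics = {
        "imputed_counts": {c: int(miss_mask[c].sum()) for c in vital_cols},
        "iterations": 0,
        "converged": True,
        "change_trajectory": [],
    }
    if not to_impute:
        return out, diagnostics

    predictors = _predictor_frame(out, spec)
    X = out[predictors].astype(float).copy()
    # initial fill: column means (observed cells only)
    for c in to_impute:
        X.loc[miss_mask[c], c] = out[c].mean()
    # impute columns in order of increasing missingness, missForest-style
    order = sorted(to_impute, key=lambda c: miss_mask[c].sum())
    seeds = spawn_seeds(spec.seed, len(order))

    prev_filled = {c: X[c].to_numpy().copy() for c in order}
    best = {c: X[c].to_numpy().copy() for c in order}
    prev_change = np.inf
    for it in range(spec.max_iterations):
        for c, s in zip(order, seeds):
            mask = miss_mask[c]
            others = [p for p in predictors if p != c]
            rf = RandomForestRegressor(
                n_estimators=spec.n_trees, random_state=s, n_jobs=1
            )
            rf.fit(X.loc[~mask, others], X.loc[~mask, c])
            X.loc[mask, c] = rf.predict(X.loc[mask, others])
        num = den = 0.0
        for c in order:
            cur = X[c].to_numpy()
            num += float(((cur - prev_filled[c]) ** 2).sum())
            den += float((cur**2).sum())
        change = num / den if den > 0 else 0.0
        diagnostics["change_trajectory"].append(change)
        diagnostics["iterations"] = it + 1
        if it > 0 and change >= prev_change:
            # the previous iteration was the best; keep it (missForest rule)
            for c in order:
                X[c] = prev_filled[c]
            break
        best = {c: X[c].to_numpy().copy() for c in order}
        if change <= spec.convergence_tol:
            break
        prev_filled = {c: X[c].to_numpy().copy() for c in order}
        prev_change = change
    else:
        diagnostics["converged"] = False
        for c in order:
            X[c] = best[c]

    for c in vital_cols:
        filled = X[c].to_numpy()
        if c.startswith("gcs"):
            filled = np.clip(np.rint(filled), 3, 15)
        # observed cells stay bitwise identical
        out[c] = np.where(miss_mask[c], filled, out[c].to_numpy())
    return out, diagnostics


def multiple_impute(
    cohort: pd.DataFrame, spec: ImputationSpec | None = None
) -> list[tuple[pd.DataFrame, dict]]:
    """Generate ``spec.n_datasets`` independently seeded completed datasets.

    Downstream pooling is left to the caller; the pipeline default is a
    single completed dataset.
    """
    spec = spec or ImputationSpec()
    seeds = spawn_seeds(spec.seed, spec.n_datasets)
    return [
        fit_impute(cohort, ImputationSpec(
            n_trees=spec.n_trees,
            max_iterations=spec.max_iterations,
            convergence_tol=spec.convergence_tol,
            seed=s,
            include_outcomes_as_predictors=spec.include_outcomes_as_predictors,
        ))
        for s in seeds
    ]
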