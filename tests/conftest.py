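"""Shared fixtures: small deterministic cohorts and a fixed paired-score dataset."""

import numpy as np
import pandas as pd
import pytest

from sepsisscreen import default_config, generate_cohort
from sepsisscreen.config import STAGES, VITALS
from sepsisscreen.surveillance import label_cohort


def no_missing_rates():
    return {v: {s: 0.0 for s in STAGES} for v in VITALS}


@pytest.fixture(scope="session")
def small_cohort():
    """600-patient default-law cohort (with missingness)."""
    return generate_cohort(default_config(seed=42).replace(n_patients=600))


@pytest.fixture(scope="session")
def complete_cohort():
    """600-patient cohort with no missing vitals."""
    cfg = default_config(seed=11).replace(
        n_patients=600, missingness_rates=no_missing_rates()
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def labelled_complete_cohort(complete_cohort):
    df, _ = label_cohort(complete_cohort)
    return df


@pytest.fixture()
def paired_scores():
    """Fixed 20-patient paired integer scores with frozen external oracle values.

    The DeLong AUC variances, CI and paired-test statistic for this dataset
    were computed independently with R pROC 1.19 (method='delong') and frozen.
    """
    labels = np.array([0] * 12 + [1] * 8, dtype=bool)
    a = np.array([0, 1, 0, 2, 1, 1, 0, 3, 1, 2, 0, 1, 2, 1, 3, 2, 2, 1, 3, 2])
    b = np.array([1, 0, 0, 1, 2, 0, 1, 1, 0, 2, 1, 0, 1, 2, 2, 3, 1, 2, 2, 3])
    oracle = {
        "auc_a": 0.7916666667,
        "auc_b": 0.8645833333,
        "var_a": 0.0095824315,
        "var_b": 0.0056113591,
        "ci_a": (0.5998059989, 0.9835273345),
        "z": -0.6251579457,
        "p": 0.5318674000,
    }
    return a, b, labels, oracle


def make_record(**overrides) -> pd.Series:
    """One complete, eligible patient record for rule-level tests."""
    rec = {
        "id": "X1", "age": 70, "male": True,
        "chief_complaint_fever": False, "ed_infection_diagnosis": True,
        "trauma": False, "cardiac_arrest": False, "death_on_arrival": False,
        "transfer_out": False, "oxygen_therapy": False,
    }
    defaults = {"sbp": 120.0, "dbp": 70.0, "hr": 90.0, "rr": 18.0,
                "bt": 37.0, "gcs": 15.0, "spo2": 97.0}
    for s in STAGES:
        for v in VITALS:
            rec[f"{v}_{s}"] = defaults[v]
    rec.update(overrides)
    return pd.Series(rec)
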