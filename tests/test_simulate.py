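"""Generator properties: determinism, marginal/correlation/missingness recovery,
and agreement between the sampled cohorts and the closed-form score law."""

import numpy as np
import pandas as pd
import pytest

from conftest import no_missing_rates
from sepsisscreen import (
    SimConfig,
    default_config,
    generate_cohort,
    read_cohort,
    true_auc,
    write_cohort,
)
from sepsisscreen.config import CONTINUOUS_VITALS, STAGES, VITALS
from sepsisscreen.errors import ConfigurationError
from sepsisscreen.qsofa import score_cohort
from sepsisscreen.simulate import combined_score_pmf


def test_same_seed_identical_cohort():
    cfg = default_config(seed=7).replace(n_patients=300)
    assert generate_cohort(cfg).equals(generate_cohort(cfg))


def test_different_seed_differs():
    a = generate_cohort(default_config(seed=1).replace(n_patients=200))
    b = generate_cohort(default_config(seed=2).replace(n_patients=200))
    assert not a.equals(b)


def test_prevalences_within_three_binomial_sds():
    cfg = default_config(seed=5)  # n = 2407
    df = generate_cohort(cfg)
    n = len(df)
    for col, p in (
        ("sepsis_true", cfg.sepsis_prev),
        ("septic_shock_true", cfg.shock_prev),
        ("died_in_hospital", cfg.mortality_prev),
    ):
        sd = np.sqrt(n * p * (1 - p))
        assert abs(df[col].sum() - n * p) <= 3 * sd, col


def test_sepsis_count_near_expected_at_study_scale():
    cfg = default_config(seed=3)
    df = generate_cohort(cfg)
    sd = np.sqrt(2407 * 0.15 * 0.85)  # ~17.5
    assert abs(df["sepsis_true"].sum() - 0.15 * 2407) <= 3 * sd


def test_stage_correlation_recovery():
    cfg = default_config(seed=9).replace(
        n_patients=2500, missingness_rates=no_missing_rates()
    )
    df = generate_cohort(cfg)
    for v in CONTINUOUS_VITALS:
        r = np.corrcoef(df[f"{v}_pre"], df[f"{v}_ed"])[0, 1]
        assert abs(r - cfg.stage_correlation) < 0.05, v


def test_missingness_rates_recovered():
    cfg = default_config(seed=13)
    df = generate_cohort(cfg)
    n = len(df)
    for v in VITALS:
        for s in STAGES:
            rate = cfg.missingness_rates[v][s]
            sd = np.sqrt(n * rate * (1 - rate))
            assert abs(df[f"{v}_{s}"].isna().sum() - n * rate) <= 3 * sd, (v, s)


def test_zero_missingness_gives_complete_vitals():
    cfg = default_config(seed=1).replace(
        n_patients=300, missingness_rates=no_missing_rates()
    )
    df = generate_cohort(cfg)
    cols = [f"{v}_{s}" for v in VITALS for s in STAGES]
    assert df[cols].notna().all().all()


def test_marginal_medians_within_reported_iqr():
    """At study scale the mixture marginals stay inside the target IQR bands."""
    cfg = default_config(seed=21)
    df = generate_cohort(cfg)
    for v in CONTINUOUS_VITALS:
        for s in STAGES:
            spec = cfg.vital_params[v][s]
            med = df[f"{v}_{s}"].median()
            lo = spec.median - spec.iqr / 2
            hi = spec.median + spec.iqr / 2
            assert lo <= med <= hi, (v, s, med)


def test_ams_marginal_matches_target():
    cfg = default_config(seed=8).replace(missingness_rates=no_missing_rates())
    df = generate_cohort(cfg)
    for s in STAGES:
        frac = (df[f"gcs_{s}"] <= 14).mean()
        target = cfg.ams_marginal[s]
        assert abs(frac - target) < 3 * np.sqrt(target * (1 - target) / len(df))


def test_vitals_respect_bounds_and_gcs_range():
    df = generate_cohort(default_config(seed=2).replace(n_patients=500))
    assert df["gcs_pre_true"].between(3, 15).all()
    assert df["spo2_ed_true"].between(0, 100).all()
    for v in CONTINUOUS_VITALS:
        assert (df[f"{v}_pre_true"] >= 0).all()


def test_empirical_combined_auc_matches_closed_form():
    """Sampled score law agrees with the orthant-probability closed form."""
    cfg = default_config(seed=17).replace(
        n_patients=40000, missingness_rates=no_missing_rates()
    )
    df = score_cohort(generate_cohort(cfg), from_true=True)
    target = true_auc(cfg)
    from sepsisscreen import roc_auc

    est = roc_auc(df["qsofa_combined"], df["sepsis_true"])
    assert abs(est.auc - target) < 0.015


def test_combined_pmf_sums_to_one():
    pmf = combined_score_pmf(default_config())
    for status in (False, True):
        assert pmf[status].shape == (7,)
        assert pmf[status].sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "kw",
    [
        {"sepsis_prev": 1.2},
        {"stage_correlation": -0.1},
        {"n_patients": 0},
        {"shock_prev": 0.5, "sepsis_prev": 0.1},
        {"exclusion_rates": {"bogus_reason": 0.1}},
    ],
)
def test_invalid_config_rejected(kw):
    with pytest.raises(ConfigurationError):
        SimConfig(**kw)


def test_mar_mechanism_targets_ams_patients():
    cfg = default_config(seed=4).replace(missing_mechanism="mar", mar_odds_factor=4.0)
    df = generate_cohort(cfg)
    ams = df["gcs_ed_true"] <= 14
    miss_ams = df.loc[ams, "rr_ed"].isna().mean()
    miss_not = df.loc[~ams, "rr_ed"].isna().mean()
    assert miss_ams > miss_not


def test_csv_round_trip(tmp_path):
    cfg = default_config(seed=6).replace(n_patients=100)
    df = generate_cohort(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(df, path, cfg)
    back = read_cohort(path)
    assert len(back) == 100
    assert (path.parent / "cohort.csv.meta.json").exists()
    pd.testing.assert_series_equal(back["sbp_ed"], df["sbp_ed"], check_dtype=False)
    assert back["sepsis_true"].equals(df["sepsis_true"])
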