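"""Synthetic suspected-infection cohort generator.

Emulates an ambulance-transported emergency-department cohort with two-stage
(prehospital and ED) vital signs, qSOFA-relevant effect sizes for latent
sepsis, configurable missingness, and ICU-course fields that a rule-based
surveillance labeller can score.

Joint structure
---------------
Each continuous vital is drawn from a truncated normal parameterised by
(median, IQR) per stage and latent sepsis status; the prehospital and ED
values of the same vital share a Gaussian copula with correlation
``stage_correlation``.  Altered mental status (AMS, GCS <= 14) uses a latent
bivariate-normal threshold model; conditional on AMS the GCS depth (3-14) is
mapped from the same latent variable, so stage-to-stage GCS changes are
coherent.  Because the copula is Gaussian and each qSOFA component is a
threshold indicator, the joint law of the (prehospital, ED) qSOFA pair given
sepsis status has a closed form (bivariate-normal orthant probabilities);
:func:`stage_score_joint_pmf` and :func:`true_auc` expose it so tests can
compare empirical estimates against the exact truth implied by the generator.
The closed form refers to scores computed from complete (pre-missingness)
vitals, which the generator also records as ``*_true`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CONTINUOUS_VITALS,
    EXCLUSION_REASONS,
    QSOFA_GCS_MAX,
    QSOFA_RR_MIN,
    QSOFA_SBP_MAX,
    STAGES,
    VITALS,
    SimConfig,
    config_to_dict,
    spawn_seeds,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "default_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "stage_score_joint_pmf",
    "combined_score_pmf",
    "true_auc",
    "true_sensitivity",
    "true_added_capture_fraction",
    "COLUMN_DICTIONARY",
]

# GCS depth distribution conditional on AMS: geometric-type decay from 14
# downwards (most altered patients are mildly altered).
_GCS_DECAY = 0.72
_GCS_VALUES = np.arange(3, 15)
_GCS_WEIGHTS = _GCS_DECAY ** (14 - _GCS_VALUES)
_GCS_WEIGHTS = _GCS_WEIGHTS / _GCS_WEIGHTS.sum()
_GCS_CDF = np.cumsum(_GCS_WEIGHTS)

FLAG_COLS = (
    "male", "chief_complaint_fever", "ed_infection_diagnosis", "trauma",
    "cardiac_arrest", "death_on_arrival", "transfer_out", "oxygen_therapy",
    "icu_admitted", "vasopressor", "ventilation", "esrd",
    "died_in_hospital", "sepsis_true", "septic_shock_true",
)
COURSE_FLOAT_COLS = (
    "blood_culture_day", "antimicrobial_days", "vasopressor_day",
    "ventilation_day", "lactate_max", "lactate_day",
    "creatinine_baseline", "creatinine_peak",
    "bilirubin_baseline", "bilirubin_peak",
    "platelet_baseline", "platelet_nadir",
)

COLUMN_DICTIONARY = {
    "id": "opaque patient identifier",
    "age": "age in completed years",
    "male": "1 if male",
    "chief_complaint_fever": "ambulance chief complaint of fever",
    "ed_infection_diagnosis": "ED physician diagnosis of infection",
    "trauma": "trauma presentation (exclusion)",
    "cardiac_arrest": "cardiac arrest (exclusion)",
    "death_on_arrival": "died immediately upon ED arrival (exclusion)",
    "transfer_out": "transported to another hospital (exclusion)",
    "oxygen_therapy": "receipt of oxygen therapy on ED arrival",
    "injected_exclusion": "simulation ground truth: injected exclusion reason ('' = eligible)",
    **{
        f"{v}_{s}": f"{v} at {'prehospital' if s == 'pre' else 'ED'} stage "
        "(empty = missing)"
        for v in VITALS for s in STAGES
    },
    **{
        f"{v}_{s}_true": "simulation ground truth (pre-missingness) value"
        for v in VITALS for s in STAGES
    },
    "icu_admitted": "admitted to ICU (ICU-course fields recorded)",
    "blood_culture_day": "hospital day a blood culture was obtained (empty = none)",
    "antimicrobial_days": "count of qualifying antimicrobial days",
    "vasopressor": "vasopressor initiated",
    "vasopressor_day": "day of vasopressor initiation",
    "ventilation": "mechanical ventilation initiated",
    "ventilation_day": "day of ventilation initiation",
    "lactate_max": "peak serum lactate, mmol/L",
    "lactate_day": "day of peak lactate",
    "creatinine_baseline": "baseline serum creatinine, mg/dL",
    "creatinine_peak": "peak serum creatinine, mg/dL",
    "bilirubin_baseline": "baseline total bilirubin, mg/dL",
    "bilirubin_peak": "peak total bilirubin, mg/dL",
    "platelet_baseline": "baseline platelet count, 10^3/uL",
    "platelet_nadir": "nadir platelet count, 10^3/uL",
    "esrd": "end-stage renal disease (creatinine criterion excluded)",
    "died_in_hospital": "in-hospital death (recorded disposition)",
    "sepsis_true": "simulation ground truth: latent sepsis state",
    "septic_shock_true": "simulation ground truth: latent septic shock state",
}


def default_config(seed: int = 0) -> SimConfig:
    """The default study-shaped generator configuration (n = 2407)."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# sampling helpers


def _truncnorm(spec, sepsis: np.ndarray):
    loc = np.where(sepsis, spec.loc(True), spec.loc(False))
    a = (spec.lo - loc) / spec.scale
    b = (spec.hi - loc) / spec.scale
    return a, b, loc, spec.scale


def _sample_vital_pair(rng, spec_pre, spec_ed, sepsis, rho):
    """Correlated (prehospital, ED) truncated-normal pair via Gaussian copula."""
    n = sepsis.size
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    out = []
    for spec, z in ((spec_pre, z1), (spec_ed, z2)):
        a, b, loc, scale = _truncnorm(spec, sepsis)
        u = stats.norm.cdf(z)
        out.append(stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale))
    return out[0], out[1]


def _sample_gcs_pair(rng, config: SimConfig, sepsis):
    """AMS via a latent bivariate-normal threshold; GCS depth from the same latent."""
    n = sepsis.size
    rho = config.stage_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    gcs = {}
    for stage, z in (("pre", z1), ("ed", z2)):
        p = np.where(
            sepsis,
            config.ams_prob(stage, True),
            config.ams_prob(stage, False),
        )
        u = stats.norm.cdf(z)
        ams = u < p
        depth = np.clip(u / np.maximum(p, 1e-12), 0, 1 - 1e-12)
        g = _GCS_VALUES[np.searchsorted(_GCS_CDF, depth, side="right")]
        gcs[stage] = np.where(ams, g, 15).astype(float)
    return gcs["pre"], gcs["ed"]


def _control_death_prob(config: SimConfig) -> float:
    p = (
        config.mortality_prev
        - config.shock_prev * config.death_given_shock
        - (config.sepsis_prev - config.shock_prev) * config.death_given_sepsis
    ) / max(1.0 - config.sepsis_prev, 1e-12)
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(
            "mortality_prev is inconsistent with the conditional death "
            f"probabilities (implied control death probability {p:.3f})"
        )
    return p


def _qualifying_course(rng, df, idx, shock):
    """ICU course satisfying the surveillance rule (default thresholds)."""
    m = idx.sum()
    culture = rng.integers(0, 3, m).astype(float)
    df.loc[idx, "icu_admitted"] = True
    df.loc[idx, "blood_culture_day"] = culture
    df.loc[idx, "antimicrobial_days"] = 4 + rng.poisson(2.0, m)
    # lactate >= 2 within the window is the guaranteed organ-dysfunction
    # criterion; vasopressors are reserved for latent shock so that the
    # Sepsis-3-consistent shock rule also recovers the latent state exactly.
    df.loc[idx, "lactate_max"] = 2.0 + rng.exponential(1.5, m)
    df.loc[idx, "lactate_day"] = np.clip(culture + rng.integers(-2, 3, m), 0, None)
    sh = shock[idx]
    vday = np.where(sh, np.clip(culture + rng.integers(-2, 3, m), 0, None), np.nan)
    df.loc[idx, "vasopressor"] = sh
    df.loc[idx, "vasopressor_day"] = vday
    vent = sh & (rng.random(m) < 0.5)
    df.loc[idx, "ventilation"] = vent
    df.loc[idx, "ventilation_day"] = np.where(
        vent, np.clip(culture + rng.integers(-2, 3, m), 0, None), np.nan
    )
    # optional extra dysfunction criteria for provenance diversity
    creat_base = rng.lognormal(-0.2, 0.3, m)
    creat_double = rng.random(m) < 0.4
    df.loc[idx, "creatinine_baseline"] = creat_base
    df.loc[idx, "creatinine_peak"] = creat_base * np.where(
        creat_double, rng.uniform(2.0, 4.0, m), rng.uniform(1.0, 1.7, m)
    )
    bili_base = rng.uniform(0.4, 1.0, m)
    bili_up = rng.random(m) < 0.25
    df.loc[idx, "bilirubin_baseline"] = bili_base
    df.loc[idx, "bilirubin_peak"] = np.where(
        bili_up, np.maximum(2.0, bili_base * 2.2), bili_base * rng.uniform(1.0, 1.8, m)
    )
    plt_base = rng.uniform(150, 350, m)
    plt_drop = rng.random(m) < 0.25
    df.loc[idx, "platelet_baseline"] = plt_base
    df.loc[idx, "platelet_nadir"] = np.where(
        plt_drop,
        np.minimum(plt_base * rng.uniform(0.2, 0.45, m), 95.0),
        plt_base * rng.uniform(0.6, 1.0, m),
    )


def _nonqualifying_course(rng, df, idx):
    """ICU course that fails the infection clause (antimicrobials < 4 days)."""
    m = idx.sum()
    has_culture = rng.random(m) < 0.5
    culture = np.where(has_culture, rng.integers(0, 3, m).astype(float), np.nan)
    df.loc[idx, "icu_admitted"] = True
    df.loc[idx, "blood_culture_day"] = culture
    df.loc[idx, "antimicrobial_days"] = rng.integers(0, 4, m)
    has_lact = rng.random(m) < 0.7
    df.loc[idx, "lactate_max"] = np.where(has_lact, rng.uniform(0.5, 1.9, m), np.nan)
    df.loc[idx, "lactate_day"] = np.where(has_lact, 0.0, np.nan)
    creat_base = rng.lognormal(-0.2, 0.3, m)
    df.loc[idx, "creatinine_baseline"] = creat_base
    df.loc[idx, "creatinine_peak"] = creat_base * rng.uniform(1.0, 1.6, m)
    bili_base = rng.uniform(0.4, 1.0, m)
    df.loc[idx, "bilirubin_baseline"] = bili_base
    df.loc[idx, "bilirubin_peak"] = bili_base * rng.uniform(1.0, 1.8, m)
    plt_base = rng.uniform(150, 350, m)
    df.loc[idx, "platelet_baseline"] = plt_base
    df.loc[idx, "platelet_nadir"] = plt_base * rng.uniform(0.7, 1.0, m)
    df.loc[idx, "esrd"] = rng.random(m) < 0.03


# ---------------------------------------------------------------------------
# generator


def generate_cohort(config: SimConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort of ``config.n_patients`` patient records.

    Deterministic for a given config (including its seed).  Returns a
    DataFrame with the columns of :data:`COLUMN_DICTIONARY`; missing vitals
    are NaN.  Ground-truth (pre-missingness) vitals and latent outcome states
    are kept in ``*_true`` columns for validation work and are ignored by the
    analysis pipeline.
    """
    config = default_config() if config is None else config
    config.validate()
    seeds = spawn_seeds(config.seed, 6)
    rng_outcome = np.random.default_rng(seeds[0])
    rng_vitals = np.random.default_rng(seeds[1])
    rng_miss = np.random.default_rng(seeds[2])
    rng_course = np.random.default_rng(seeds[3])
    rng_flags = np.random.default_rng(seeds[4])
    rng_excl = np.random.default_rng(seeds[5])
    n = config.n_patients

    sepsis = rng_outcome.random(n) < config.sepsis_prev
    p_shock = config.shock_prev / config.sepsis_prev if config.sepsis_prev > 0 else 0.0
    shock = sepsis & (rng_outcome.random(n) < p_shock)
    p_death = np.where(
        shock, config.death_given_shock,
        np.where(sepsis, config.death_given_sepsis, _control_death_prob(config)),
    )
    died = rng_outcome.random(n) < p_death

    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(n)]})
    age_spec_a, age_spec_b = (18 - 78) / 13.3, (105 - 78) / 13.3
    df["age"] = np.floor(
        stats.truncnorm.ppf(rng_flags.random(n), age_spec_a, age_spec_b, loc=78, scale=13.3)
    )
    df["male"] = rng_flags.random(n) < 0.58
    df["chief_complaint_fever"] = rng_flags.random(n) < 0.55
    df["ed_infection_diagnosis"] = rng_flags.random(n) < (0.45 + 0.25 * sepsis)
    for c in ("trauma", "cardiac_arrest", "death_on_arrival", "transfer_out"):
        df[c] = False
    df["oxygen_therapy"] = rng_flags.random(n) < (0.25 + 0.30 * sepsis)

    rho = config.stage_correlation
    for v in CONTINUOUS_VITALS:
        pre, ed = _sample_vital_pair(
            rng_vitals, config.vital_params[v]["pre"], config.vital_params[v]["ed"],
            sepsis, rho,
        )
        df[f"{v}_pre_true"], df[f"{v}_ed_true"] = pre, ed
    gpre, ged = _sample_gcs_pair(rng_vitals, config, sepsis)
    df["gcs_pre_true"], df["gcs_ed_true"] = gpre, ged

    # missingness (MCAR by default; MAR multiplies the odds for AMS patients)
    for v in VITALS:
        for s in STAGES:
            rate = config.missingness_rates.get(v, {}).get(s, 0.0)
            p = np.full(n, rate)
            if config.missing_mechanism == "mar" and rate > 0:
                ams = df[f"gcs_{s}_true"].to_numpy() <= QSOFA_GCS_MAX
                odds = rate / (1 - rate) * config.mar_odds_factor
                p = np.where(ams, odds / (1 + odds), rate)
            miss = rng_miss.random(n) < p
            df[f"{v}_{s}"] = np.where(miss, np.nan, df[f"{v}_{s}_true"])

    # ICU course.  Labeller fidelity: sensitivity demotes latent cases to a
    # non-qualifying course, 1-specificity promotes latent controls.
    df["icu_admitted"] = False
    for c in ("vasopressor", "ventilation", "esrd"):
        df[c] = False
    for c in COURSE_FLOAT_COLS:
        df[c] = np.nan
    df["antimicrobial_days"] = 0.0
    qualifies = np.where(
        sepsis,
        rng_course.random(n) < config.labeler_sensitivity,
        rng_course.random(n) > config.labeler_specificity,
    )
    control_icu = (~sepsis) & (~qualifies) & (rng_course.random(n) < 0.35)
    demoted = sepsis & ~qualifies
    if qualifies.any():
        _qualifying_course(rng_course, df, qualifies, shock)
    nonq = control_icu | demoted
    if nonq.any():
        _nonqualifying_course(rng_course, df, nonq)

    df["died_in_hospital"] = died
    df["sepsis_true"] = sepsis
    df["septic_shock_true"] = shock & qualifies

    # inject ineligible records (flow testing); one reason per record,
    # assigned in precedence order
    df["injected_exclusion"] = ""
    taken = np.zeros(n, dtype=bool)
    for reason in EXCLUSION_REASONS:
        rate = config.exclusion_rates.get(reason, 0.0)
        if rate <= 0:
            continue
        pick = (rng_excl.random(n) < rate) & ~taken
        taken |= pick
        df.loc[pick, "injected_exclusion"] = reason
        if reason == "age_lt_18":
            df.loc[pick, "age"] = rng_excl.integers(1, 18, pick.sum())
        elif reason == "no_suspected_infection":
            df.loc[pick, ["chief_complaint_fever", "ed_infection_diagnosis"]] = False
            df.loc[pick, "bt_ed"] = 36.5
        elif reason == "insufficient_vitals":
            drop = [f"{v}_pre" for v in VITALS if v != "hr"]  # 6 of 7 missing
            df.loc[pick, drop] = np.nan
        else:
            df.loc[pick, reason] = True

    # guarantee the suspected-infection gate for every non-injected record
    suspected = (
        df["chief_complaint_fever"]
        | df["ed_infection_diagnosis"]
        | (df["bt_ed"] >= 37.5)
    )
    force = ~suspected & (df["injected_exclusion"] != "no_suspected_infection")
    df.loc[force, "ed_infection_diagnosis"] = True
    return df


# ---------------------------------------------------------------------------
# CSV I/O (empty-string nulls, sidecar metadata)


def write_cohort(df: pd.DataFrame, path: str | Path, config: SimConfig | None = None) -> None:
    """Write a cohort as CSV (empty-string nulls) plus a JSON metadata sidecar."""
    path = Path(path)
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == bool:
            out[c] = out[c].astype(int)
    out.to_csv(path, index=False, na_rep="", float_format="%.17g")
    meta = {
        "n_rows": int(len(df)),
        "columns": {c: COLUMN_DICTIONARY.get(c, "") for c in df.columns},
    }
    if config is not None:
        meta["seed"] = config.seed
        meta["config"] = config_to_dict(config)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made)."""
    df = pd.read_csv(
        path, dtype={"id": str, "injected_exclusion": str},
        float_precision="round_trip",
    )
    if "id" in df.columns and df["id"].duplicated().any():
        raise DataError("duplicate patient ids in cohort file")
    for c in FLAG_COLS:
        if c in df.columns:
            df[c] = df[c].fillna(0).astype(bool)
    float_cols = (
        ["age"]
        + [f"{v}_{s}{t}" for v in VITALS for s in STAGES for t in ("", "_true")]
        + list(COURSE_FLOAT_COLS)
    )
    for c in float_cols:
        if c in df.columns:
            df[c] = df[c].astype(float)
    if "injected_exclusion" in df.columns:
        df["injected_exclusion"] = df["injected_exclusion"].fillna("")
    return df


# ---------------------------------------------------------------------------
# closed-form score law


def _lower_q(spec, sepsis: bool, threshold: float) -> float:
    """Standard-normal threshold equivalent to {vital <= threshold}."""
    a = (spec.lo - spec.loc(sepsis)) / spec.scale
    b = (spec.hi - spec.loc(sepsis)) / spec.scale
    p = stats.truncnorm.cdf(threshold, a, b, loc=spec.loc(sepsis), scale=spec.scale)
    return float(stats.norm.ppf(np.clip(p, 1e-15, 1 - 1e-15)))


def _pair_pmf(q_pre: float, q_ed: float, rho: float, upper: bool) -> np.ndarray:
    """2x2 pmf of the (prehospital, ED) indicator pair under a Gaussian copula."""
    if upper:  # {Z > q}  ==  {-Z < -q}; (-Z1, -Z2) keeps correlation rho
        q_pre, q_ed = -q_pre, -q_ed
    cov = [[1.0, rho], [rho, 1.0]]
    p11 = float(stats.multivariate_normal(mean=[0, 0], cov=cov).cdf([q_pre, q_ed]))
    p1_ = float(stats.norm.cdf(q_pre))
    p_1 = float(stats.norm.cdf(q_ed))
    pmf = np.array([[1 - p1_ - p_1 + p11, p_1 - p11], [p1_ - p11, p11]])
    return np.clip(pmf, 0.0, 1.0)


def stage_score_joint_pmf(config: SimConfig) -> dict[bool, np.ndarray]:
    """Exact 4x4 joint pmf of (prehospital qSOFA, ED qSOFA) given sepsis status.

    Computed from bivariate-normal orthant probabilities of the three
    component indicators (hypotension, tachypnoea, AMS), which are mutually
    independent given sepsis status under the generator's law.
    """
    rho = config.stage_correlation
    out = {}
    for status in (False, True):
        pairs = []
        sbp = config.vital_params["sbp"]
        pairs.append(_pair_pmf(
            _lower_q(sbp["pre"], status, QSOFA_SBP_MAX),
            _lower_q(sbp["ed"], status, QSOFA_SBP_MAX), rho, upper=False,
        ))
        rr = config.vital_params["rr"]
        pairs.append(_pair_pmf(
            _lower_q(rr["pre"], status, QSOFA_RR_MIN),
            _lower_q(rr["ed"], status, QSOFA_RR_MIN), rho, upper=True,
        ))
        q_ams = [
            float(stats.norm.ppf(np.clip(config.ams_prob(s, status), 1e-15, 1 - 1e-15)))
            for s in STAGES
        ]
        pairs.append(_pair_pmf(q_ams[0], q_ams[1], rho, upper=False))

        joint = np.ones((1, 1))
        for pmf in pairs:
            new = np.zeros((joint.shape[0] + 1, joint.shape[1] + 1))
            for i in range(2):
                for j in range(2):
                    new[i:i + joint.shape[0], j:j + joint.shape[1]] += joint * pmf[i, j]
            joint = new
        out[status] = joint
    return out


def combined_score_pmf(config: SimConfig) -> dict[bool, np.ndarray]:
    """Exact pmf of combined qSOFA (0-6) given sepsis status."""
    joint = stage_score_joint_pmf(config)
    out = {}
    for status, j in joint.items():
        pmf = np.zeros(7)
        for a in range(4):
            for b in range(4):
                pmf[a + b] += j[a, b]
        out[status] = pmf
    return out


def _pmf_auc(p_case: np.ndarray, p_ctrl: np.ndarray) -> float:
    gt = sum(p_case[i] * p_ctrl[j] for i in range(len(p_case)) for j in range(i))
    eq = float(np.dot(p_case, p_ctrl))
    return float(gt + 0.5 * eq)


def true_auc(config: SimConfig, score: str = "qsofa_combined") -> float:
    """Closed-form AUC of a score for latent sepsis under the generator's law."""
    joint = stage_score_joint_pmf(config)
    if score == "qsofa_combined":
        pmf = combined_score_pmf(config)
        return _pmf_auc(pmf[True], pmf[False])
    axis = {"qsofa_pre": 1, "qsofa_ed": 0}[score]
    return _pmf_auc(joint[True].sum(axis=axis), joint[False].sum(axis=axis))


def true_sensitivity(config: SimConfig, score: str, cutoff: int) -> float:
    """Closed-form P(score >= cutoff | latent sepsis)."""
    if score == "qsofa_combined":
        pmf = combined_score_pmf(config)[True]
    else:
        axis = {"qsofa_pre": 1, "qsofa_ed": 0}[score]
        pmf = stage_score_joint_pmf(config)[True].sum(axis=axis)
    return float(pmf[cutoff:].sum())


def true_added_capture_fraction(
    config: SimConfig, ed_cutoff: int = 2, combined_cutoff: int = 3
) -> float:
    """Closed-form P(combined >= c AND ED < c_ed | latent sepsis)."""
    j = stage_score_joint_pmf(config)[True]
    total = 0.0
    for a in range(4):
        for b in range(4):
            if b < ed_cutoff and a + b >= combined_cutoff:
                total += j[a, b]
    return float(total)
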