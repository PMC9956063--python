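"""ROC/DeLong machinery and the accuracy/transition/added-capture statistics.

The c-statistic is checked against exhaustive case-control pair counting; the
DeLong variance against a delete-one jackknife and against values frozen from
R pROC; the paired test against a stratified-bootstrap oracle.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, rankdata

from sepsisscreen import (
    accuracy_at_cutoff,
    accuracy_table,
    added_capture,
    delong_test,
    roc_auc,
    transition_table,
)
from sepsisscreen.errors import DataError, DegenerateInputError
from sepsisscreen.evaluate import roc_coordinates
from sepsisscreen.qsofa import CutoffRule, score_cohort


def pair_counting_auc(scores, labels):
    """Independent oracle: exhaustive case-control pair counting, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, ctrls = scores[labels], scores[~labels]
    wins = ties = 0
    for c in cases:
        for d in ctrls:
            if c > d:
                wins += 1
            elif c == d:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(ctrls))


# -- c-statistic ------------------------------------------------------------


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),          # perfect separation
        ([2, 2, 2, 2], [0, 1, 0, 1], 0.5),          # complete ties
        ([0, 1, 1, 2, 3], [0, 0, 1, 1, 1], 11 / 12),  # brute-forced by hand
        ([4, 3, 2, 1], [0, 0, 1, 1], 0.0),          # perfectly reversed
    ],
)
def test_auc_known_values(scores, labels, expected):
    assert roc_auc(scores, np.array(labels, bool)).auc == pytest.approx(
        expected, abs=1e-12
    )


@given(st.data())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_auc_equals_pair_counting_oracle(data):
    n = data.draw(st.integers(4, 30))
    labels = np.array(data.draw(
        st.lists(st.booleans(), min_size=n, max_size=n)
    ))
    if labels.all() or not labels.any():
        labels[0], labels[-1] = True, False
    scores = np.array(data.draw(
        st.lists(st.integers(0, 6), min_size=n, max_size=n)
    ))
    est = roc_auc(scores, labels)
    assert est.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
    if np.isfinite(est.ci95[0]):
        assert est.ci95[0] <= est.auc <= est.ci95[1]


def test_auc_single_class_rejected():
    with pytest.raises(DegenerateInputError):
        roc_auc([1, 2, 3], np.array([True, True, True]))


def test_auc_matches_frozen_external_oracle(paired_scores):
    a, b, labels, oracle = paired_scores
    ea, eb = roc_auc(a, labels), roc_auc(b, labels)
    assert ea.auc == pytest.approx(oracle["auc_a"], abs=1e-9)
    assert eb.auc == pytest.approx(oracle["auc_b"], abs=1e-9)
    assert ea.variance == pytest.approx(oracle["var_a"], abs=1e-9)
    assert eb.variance == pytest.approx(oracle["var_b"], abs=1e-9)
    assert ea.ci95 == pytest.approx(oracle["ci_a"], abs=1e-9)


def test_delong_variance_close_to_jackknife():
    """DeLong structural-components variance tracks the delete-one jackknife."""

    def mw_auc(s, y):
        r = rankdata(s)
        m, nn = y.sum(), (~y).sum()
        return (r[y].sum() - m * (m + 1) / 2) / (m * nn)

    rng = np.random.default_rng(5)
    for _ in range(50):
        n = 50
        y = np.zeros(n, bool)
        y[:25] = True
        s = rng.standard_normal(n) + y * 1.0
        v_delong = roc_auc(s, y).variance
        theta = mw_auc(s, y)
        loo = np.array([
            mw_auc(np.delete(s, i), np.delete(y, i)) for i in range(n)
        ])
        pseudo = n * theta - (n - 1) * loo
        v_jack = pseudo.var(ddof=1) / n
        assert abs(v_jack - v_delong) / v_delong < 0.10


# -- paired DeLong test -----------------------------------------------------


def test_delong_self_comparison_is_null(paired_scores):
    a, _, labels, _ = paired_scores
    z, p = delong_test(a, a, labels)
    assert z == 0.0 and p == 1.0


def test_delong_antisymmetric(paired_scores):
    a, b, labels, _ = paired_scores
    z1, p1 = delong_test(a, b, labels)
    z2, p2 = delong_test(b, a, labels)
    assert z1 == pytest.approx(-z2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_delong_matches_frozen_external_oracle(paired_scores):
    a, b, labels, oracle = paired_scores
    z, p = delong_test(a, b, labels)
    assert z == pytest.approx(oracle["z"], abs=1e-9)
    assert p == pytest.approx(oracle["p"], abs=1e-9)


def test_delong_matches_stratified_bootstrap(paired_scores):
    """Paired p within 0.02 of a 10,000-replicate stratified-bootstrap p."""
    a, b, labels, _ = paired_scores

    def mw_auc(s, y):
        r = rankdata(s)
        m, nn = y.sum(), (~y).sum()
        return (r[y].sum() - m * (m + 1) / 2) / (m * nn)

    rng = np.random.default_rng(7)
    cases, ctrls = np.where(labels)[0], np.where(~labels)[0]
    diffs = np.empty(10000)
    for i in range(10000):
        idx = np.concatenate(
            [rng.choice(cases, cases.size), rng.choice(ctrls, ctrls.size)]
        )
        diffs[i] = mw_auc(a[idx], labels[idx]) - mw_auc(b[idx], labels[idx])
    obs = mw_auc(a, labels) - mw_auc(b, labels)
    p_boot = 2 * norm.sf(abs(obs) / diffs.std())
    _, p = delong_test(a, b, labels)
    assert abs(p - p_boot) < 0.02


def test_delong_length_mismatch_rejected(paired_scores):
    a, b, labels, _ = paired_scores
    with pytest.raises(DataError):
        delong_test(a[:-1], b, labels)


# -- per-cutoff accuracy ----------------------------------------------------


def test_accuracy_metrics_arithmetic():
    # tp 2, fn 1, fp 3, tn 4
    scores = np.array([2, 2, 1, 2, 2, 2, 1, 1, 1, 1])
    labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], bool)
    m = accuracy_at_cutoff(scores, labels, CutoffRule("qsofa_ed", 2))
    assert (m.tp, m.fn, m.fp, m.tn) == (2, 1, 3, 4)
    assert m.sensitivity == pytest.approx(2 / 3)
    assert m.specificity == pytest.approx(4 / 7)
    assert m.ppv == pytest.approx(2 / 5)
    assert m.npv == pytest.approx(4 / 5)
    assert m.tp + m.fp + m.fn + m.tn == len(scores)


def test_cutoff_below_min_everyone_positive():
    scores = np.array([1, 2, 3, 2])
    labels = np.array([0, 1, 1, 0], bool)
    m = accuracy_at_cutoff(scores, labels, CutoffRule("qsofa_ed", 1))
    assert m.sensitivity == 1.0 and m.specificity == 0.0
    # NPV undefined (no test-negatives), flagged rather than zeroed
    assert np.isnan(m.npv) and "npv" in m.undefined


def test_wilson_interval_used():
    from statsmodels.stats.proportion import proportion_confint

    scores = np.array([2] * 8 + [1] * 12)
    labels = np.array([1] * 10 + [0] * 10, bool)
    m = accuracy_at_cutoff(scores, labels, CutoffRule("qsofa_ed", 2))
    lo, hi = proportion_confint(m.tp, m.tp + m.fn, method="wilson")
    assert m.sensitivity_ci == pytest.approx((lo, hi))


def test_accuracy_sensitivity_matches_generator_closed_form():
    """Empirical sensitivity within 3 SE of the generator's conditional law."""
    from sepsisscreen import default_config, generate_cohort
    from sepsisscreen.simulate import true_sensitivity

    cfg = default_config(seed=19).replace(n_patients=5000)
    df = score_cohort(generate_cohort(cfg), from_true=True)
    target = true_sensitivity(cfg, "qsofa_combined", 3)
    m = accuracy_at_cutoff(
        df["qsofa_combined"], df["sepsis_true"], CutoffRule("qsofa_combined", 3)
    )
    n_cases = m.tp + m.fn
    se = np.sqrt(target * (1 - target) / n_cases)
    assert abs(m.sensitivity - target) <= 3 * se


def _scored_fixture(labelled_complete_cohort):
    return score_cohort(labelled_complete_cohort)


def test_accuracy_table_shape_and_monotonicity(labelled_complete_cohort):
    scored = _scored_fixture(labelled_complete_cohort)
    t = accuracy_table(scored, "qsofa_combined", "sepsis", cutoffs=(1, 2, 3, 4, 5, 6))
    assert len(t.rows) == 6
    sens = [r.sensitivity for r in t.rows]
    spec = [r.specificity for r in t.rows]
    assert all(a >= b for a, b in zip(sens, sens[1:]))   # non-increasing
    assert all(a <= b for a, b in zip(spec, spec[1:]))   # non-decreasing
    # Bayes identity holds exactly on every row built from one 2x2 table
    prev = scored["sepsis"].mean()
    for r in t.rows:
        if np.isnan(r.ppv):
            continue
        implied = (r.sensitivity * prev) / (
            r.sensitivity * prev + (1 - r.specificity) * (1 - prev)
        )
        assert r.ppv == pytest.approx(implied, abs=1e-12)


def test_accuracy_table_reference_and_empty_cutoffs(labelled_complete_cohort):
    scored = _scored_fixture(labelled_complete_cohort)
    t_ref = accuracy_table(scored, "qsofa_ed", "sepsis", cutoffs=(1, 2, 3))
    assert t_ref.delong_p is None  # reference score compares to nothing
    t_cmb = accuracy_table(scored, "qsofa_combined", "sepsis", cutoffs=())
    assert t_cmb.rows == [] and 0 <= t_cmb.auc.auc <= 1
    assert 0 < accuracy_table(
        scored, "qsofa_pre", "sepsis", cutoffs=(2,)
    ).delong_p <= 1


def test_ppv_tends_to_prevalence_at_min_cutoff(labelled_complete_cohort):
    scored = _scored_fixture(labelled_complete_cohort)
    prev = scored["sepsis"].mean()
    # cutoff 0 would make everyone positive; cutoff 1 is the closest admissible
    m = accuracy_at_cutoff(
        scored["qsofa_combined"], scored["sepsis"].to_numpy(),
        CutoffRule("qsofa_combined", 1),
    )
    assert abs(m.ppv - prev) < 0.05


# -- transitions and added capture -----------------------------------------


def test_transition_single_patient():
    df = pd.DataFrame({"qsofa_pre": [2], "qsofa_ed": [1], "sepsis": [True]})
    t = transition_table(df, "sepsis")
    assert t.total == 1
    assert t.counts[2, 1, 1] == 1
    assert t.counts.sum() == 1


def test_transition_marginals_and_brute_force(labelled_complete_cohort):
    scored = _scored_fixture(labelled_complete_cohort)
    t = transition_table(scored, "sepsis")
    assert t.total == len(scored)
    # marginal over ED axis and outcome equals the prehospital distribution
    pre_marginal = t.counts.sum(axis=(1, 2))
    expected = scored["qsofa_pre"].value_counts().reindex(range(4), fill_value=0)
    assert (pre_marginal == expected.to_numpy()).all()
    # independent tally oracle via groupby
    grouped = scored.groupby(
        ["qsofa_pre", "qsofa_ed", "sepsis"]
    ).size()
    for (a, b, o), cnt in grouped.items():
        assert t.counts[int(a), int(b), int(o)] == cnt


def test_added_capture_rules():
    df = pd.DataFrame({
        "qsofa_pre": [2, 0, 1, 3],
        "qsofa_ed": [1, 2, 0, 2],
        "sepsis": [True, True, True, False],
    })
    df["qsofa_combined"] = df["qsofa_pre"] + df["qsofa_ed"]
    count, frac = added_capture(df, "sepsis")
    # patient 0: combined 3, ED 1 -> captured; patient 1: ED already positive;
    # patient 2: combined 1 < 3; patient 3: not outcome-positive
    assert count == 1
    assert frac == pytest.approx(1 / 3)


def test_added_capture_no_positives_flagged():
    df = pd.DataFrame({
        "qsofa_pre": [0, 1], "qsofa_ed": [0, 1], "qsofa_combined": [0, 2],
        "sepsis": [False, False],
    })
    with pytest.warns(UserWarning):
        count, frac = added_capture(df, "sepsis")
    assert count == 0 and np.isnan(frac)


def test_roc_coordinates_monotone(labelled_complete_cohort):
    scored = _scored_fixture(labelled_complete_cohort)
    roc = roc_coordinates(scored["qsofa_combined"], scored["sepsis"])
    assert (np.diff(roc["fpr"]) >= 0).all()
    assert (np.diff(roc["tpr"]) >= 0).all()
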