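"""Regression machinery: OLS against closed forms, t-test, matching, reports."""

import numpy as np
import pandas as pd
import pytest

from neoharm.phantom import SubjectMeta, sample_truth_table
from neoharm.stats import (
    fit_lm,
    harmonization_report,
    match_cohorts,
    outcome_association,
    two_sample_t,
)


def normal_equations(X, y):
    """Independent OLS oracle."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    return beta, se


# ---------------------------------------------------------------------------
# fit_lm
# ---------------------------------------------------------------------------

def test_fit_lm_noiseless_line():
    t = pd.DataFrame({"x": [0.0, 1, 2, 3, 4], "y": [3.0, 5, 7, 9, 11]})
    f = fit_lm(t, "y", ["x"])
    assert f.coef["intercept"] == pytest.approx(3.0, abs=1e-10)
    assert f.coef["x"] == pytest.approx(2.0, abs=1e-10)
    assert f.df_resid == 3


@pytest.mark.parametrize("seed", [0, 1])
def test_fit_lm_matches_normal_equations(seed):
    rng = np.random.default_rng(seed)
    n = 25
    t = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.standard_normal(n),
        "sex": rng.choice(["F", "M"], n),
    })
    t["y"] = 1.5 + 0.7 * t.a - 0.3 * t.b + 0.2 * (t.sex == "M") \
        + rng.standard_normal(n) * 0.5
    f = fit_lm(t, "y", ["a", "b", "sex"])
    X = np.column_stack([np.ones(n), t.a, t.b, (t.sex == "M").astype(float)])
    beta, se = normal_equations(X, t.y.to_numpy())
    for i, term in enumerate(["intercept", "a", "b", "sex"]):
        assert f.coef[term] == pytest.approx(beta[i], abs=1e-9)
        assert f.se[term] == pytest.approx(se[i], abs=1e-9)


def test_fit_lm_interaction_term():
    rng = np.random.default_rng(2)
    n = 30
    t = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
    t["y"] = 2.0 * t.a * t.b + rng.standard_normal(n) * 0.1
    f = fit_lm(t, "y", ["a", "b", "a:b"])
    assert f.coef["a:b"] == pytest.approx(2.0, abs=0.15)


def test_fit_lm_rank_deficiency_names_columns():
    t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                      "y": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError, match="collinear"):
        fit_lm(t, "y", ["a", "b"])


def test_fit_lm_missing_values_rejected():
    t = pd.DataFrame({"a": [1.0, np.nan, 3], "y": [1.0, 2, 3]})
    with pytest.raises(ValueError, match="missing"):
        fit_lm(t, "y", ["a"])


def test_fit_lm_two_predictor_closed_form_property():
    """Analytic two-variable regression on random tables."""
    rng = np.random.default_rng(9)
    for _ in range(5):
        n = 40
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = rng.standard_normal(n)
        t = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        f = fit_lm(t, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(n), x1, x2])
        beta, _ = normal_equations(X, y)
        assert f.coef["x1"] == pytest.approx(beta[1], abs=1e-9)
        assert f.coef["x2"] == pytest.approx(beta[2], abs=1e-9)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_two_sample_t_identical_groups():
    g = [1.0, 2.0, 3.0]
    r = two_sample_t(g, g)
    assert r["t"] == pytest.approx(0.0)
    assert r["p"] == pytest.approx(1.0)
    assert r["df"] == 4


def test_two_sample_t_matches_pooled_formula():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 3.0])
    r = two_sample_t(a, b)
    sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
    t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert r["t"] == pytest.approx(t_expected, abs=1e-12)
    assert r["df"] == 4


def test_two_sample_t_scale_invariance():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(10)
    b = rng.standard_normal(12) + 0.5
    t1 = two_sample_t(a, b)["t"]
    t2 = two_sample_t(7.0 * a, 7.0 * b)["t"]
    assert t1 == pytest.approx(t2, abs=1e-12)


def test_two_sample_t_validation():
    with pytest.raises(ValueError):
        two_sample_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _meta(ga, pma, i=0, cohort="source"):
    return SubjectMeta(id=f"m{i}", cohort=cohort, ga_weeks=ga, pma_weeks=pma,
                       sex="F")


def test_match_identical_lists_zero_distance():
    a = [_meta(30, 41, i) for i in range(5)]
    m = match_cohorts(a, a, 5)
    assert m["smd_ga"] == 0.0 and m["smd_pma"] == 0.0


def test_match_greedy_picks_closest_pair_first():
    a = [_meta(30.0, 41.0, 0), _meta(25.0, 38.0, 1)]
    b = [_meta(30.1, 41.0, 0, "target"), _meta(33.0, 44.0, 1, "target")]
    m = match_cohorts(a, b, 1)
    assert m["pairs"][0] == (0, 0)


def test_match_insufficient_subjects():
    with pytest.raises(ValueError):
        match_cohorts([_meta(30, 41)], [_meta(30, 41)], 2)


# ---------------------------------------------------------------------------
# harmonization report & type-I calibration
# ---------------------------------------------------------------------------

def _table_from_truth(tab, thickness_col):
    out = tab.rename(columns={c: c.replace("true_vol", "vol")
                              for c in tab.columns})
    out["thickness_mm"] = tab[thickness_col].to_numpy()
    return out


def test_report_lists_all_tissues_and_ct():
    tab = sample_truth_table(10, seed=0, matched=True, measured=True)
    cond = _table_from_truth(tab, "measured_thickness_mm")
    rep = harmonization_report({"naive": cond})
    assert set(rep.measure) == {"csf", "cgm", "wm", "dgm", "cerebellum",
                                "brainstem", "cortical_thickness"}


def test_report_flags_injected_ct_effect():
    tab = sample_truth_table(30, seed=1, matched=True, measured=True)
    cond = _table_from_truth(tab, "measured_thickness_mm")
    rep = harmonization_report({"naive": cond})
    row = rep[rep.measure == "cortical_thickness"].iloc[0]
    assert row["significant"]
    assert row["cohort_beta"] == pytest.approx(0.20, abs=0.07)


def test_report_requires_both_cohorts():
    tab = sample_truth_table(5, seed=2, matched=True, measured=True)
    cond = _table_from_truth(tab, "measured_thickness_mm")
    with pytest.raises(ValueError):
        harmonization_report({"bad": cond[cond.cohort == "source"]})


def test_cohort_test_type_one_error_calibrated():
    """Under the null (ground-truth thickness, no domain bias) the cohort
    test fires at ~ the nominal level."""
    rng = np.random.default_rng(11)
    hits = 0
    n_sim = 200
    for s in range(n_sim):
        tab = sample_truth_table(30, seed=s, matched=True)
        tab["thickness_mm"] = (tab["true_thickness_mm"]
                               + rng.normal(0, 0.03, len(tab)))
        f = fit_lm(tab, "thickness_mm", ["cohort", "pma_weeks", "ga_weeks", "sex"])
        hits += f.pvalue["cohort"] < 0.05
    assert 0.01 <= hits / n_sim <= 0.10


def test_beta_pma_parameter_recovery():
    """The injected PMA slope is recovered without material bias at n=60."""
    betas = []
    rng = np.random.default_rng(5)
    for s in range(20):
        tab = sample_truth_table(30, seed=100 + s, matched=True)
        tab["thickness_mm"] = (tab["true_thickness_mm"]
                               + rng.normal(0, 0.03, len(tab)))
        f = fit_lm(tab, "thickness_mm", ["cohort", "pma_weeks", "ga_weeks", "sex"])
        betas.append(f.coef["pma_weeks"])
    assert abs(np.mean(betas) - 0.04) < 0.25 * 0.04


# ---------------------------------------------------------------------------
# outcome association
# ---------------------------------------------------------------------------

def _outcome_table(n, seed, noise=0.03):
    tab = sample_truth_table(n, seed=seed, matched=False, measured=True,
                             measurement_noise_sd_mm=noise)
    tab = tab.rename(columns={c: c.replace("true_vol", "vol")
                              for c in tab.columns})
    return tab


def test_outcome_association_zero_variance_rejected():
    tab = _outcome_table(20, 0)
    tab["outcome_score"] = 5.0
    with pytest.raises(ValueError):
        outcome_association(tab, "measured_thickness_mm")


def test_outcome_association_returns_three_fits():
    tab = _outcome_table(40, 1)
    res = outcome_association(tab, "measured_thickness_mm")
    assert set(res) == {"source", "target", "pooled"}
    assert all("measured_thickness_mm" in r.coef for r in res.values())


def test_outcome_spurious_pooled_association_mechanism():
    """Cohort-biased CT + cohort-shifted outcomes with no true link: the
    pooled fit goes spuriously negative while per-cohort fits stay null."""
    pooled_sig = per_cohort_ns = harm_ns = 0
    for s in range(10):
        tab = _outcome_table(3000, 777 + s)
        tab["ct_unharm"] = tab["measured_thickness_mm"]
        tab["ct_harm"] = (tab["true_thickness_mm"]
                          + np.random.default_rng(10_000 + s)
                          .normal(0, 0.03, len(tab)))
        r = outcome_association(tab, "ct_unharm")
        pooled_sig += r["pooled"].pvalue["ct_unharm"] < 0.05
        per_cohort_ns += (r["source"].pvalue["ct_unharm"] >= 0.05
                          and r["target"].pvalue["ct_unharm"] >= 0.05)
        rh = outcome_association(tab, "ct_harm")
        harm_ns += rh["pooled"].pvalue["ct_harm"] >= 0.05
    assert pooled_sig >= 8
    assert per_cohort_ns >= 8
    assert harm_ns >= 8
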