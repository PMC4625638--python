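"""Oracle and property tests for the Cox/evaluation core.

Each statistic is checked against an independent re-derivation: the Cox
coefficient against a grid-search maximizer of the partial likelihood,
the c-index against exhaustive pair enumeration, the log-rank statistic
against a hand risk-set computation, and kappa against its closed
formula on enumerated 2x2 tables.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicox import (
    SurvivalData,
    bootstrap_cindex,
    cohen_kappa,
    concordance_index,
    fit_cox,
    logrank_median_split,
    prognostic_index,
    stratified_bootstrap,
    stratified_split,
)
from omicox.survival import FitError, significance_tier

from conftest import random_survival


# ---------------------------------------------------------------------------
# independent oracles


def efron_loglik_direct(beta, x, time, event):
    """Direct Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        d = len(deaths)
        ll += beta * x[deaths].sum()
        s_risk = np.exp(beta * x[risk]).sum()
        s_dead = np.exp(beta * x[deaths]).sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_dead)
    return ll


def grid_search_beta(x, time, event, lo=-5, hi=5, steps=20001):
    grid = np.linspace(lo, hi, steps)
    vals = [efron_loglik_direct(b, x, time, event) for b in grid]
    return grid[int(np.argmax(vals))]


def cindex_bruteforce(pi, time, event):
    num = den = 0.0
    n = len(pi)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if pi[i] > pi[j]:
                    num += 1
                elif pi[i] == pi[j]:
                    num += 0.5
    return num / den


def logrank_riskset(time, event, group):
    """Two-group log-rank chi-square from the observed-minus-expected
    statistic accumulated over event-time risk sets."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n1 = int((at_risk & group).sum())
        n_tot = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & group).sum())
        o_minus_e += d1 - d * n1 / n_tot
        if n_tot > 1:
            var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# fit_cox


@pytest.mark.parametrize("seed", range(10))
def test_cox_beta_matches_grid_search(seed):
    rng = np.random.default_rng(seed)
    n = 8
    x = rng.standard_normal(n)
    sv = random_survival(rng, n)
    fit = fit_cox(x[:, None], sv)
    oracle = grid_search_beta(x, sv.time, sv.event)
    assert abs(fit.beta[0] - oracle) < 1e-3


def test_cox_null_covariate_near_zero():
    rng = np.random.default_rng(0)
    n = 400
    x = (rng.random(n) < 0.5).astype(float)
    sv = random_survival(rng, n)
    fit = fit_cox(x[:, None], sv)
    assert abs(fit.beta[0]) < 3 * fit.se[0]


def test_cox_matches_lifelines_with_ties(cohort):
    from lifelines import CoxPHFitter

    planted = cohort.truth.planted["EXPR"]
    X = cohort.matrices["EXPR"].df.T[planted]
    tied = np.ceil(cohort.survival.time / 50.0)
    sv = SurvivalData(cohort.survival.patient_ids, tied, cohort.survival.event)
    df = X.copy()
    df["T"], df["E"] = sv.time, sv.event
    ll = CoxPHFitter().fit(df, "T", "E")
    fit = fit_cox(X, sv)
    assert np.allclose(fit.beta, ll.params_.values, atol=1e-4)
    assert np.isclose(fit.log_partial_likelihood, ll.log_likelihood_, atol=1e-6)


def test_cox_collinear_duplicate_feature_is_stabilized():
    rng = np.random.default_rng(2)
    n = 60
    x = rng.standard_normal(n)
    sv = random_survival(rng, n, censor_frac=0.0)
    fit = fit_cox(np.column_stack([x, x]), sv)
    # ridge-stabilized: finite coefficients whose sum recovers the effect
    single = fit_cox(x[:, None], sv)
    assert np.all(np.isfinite(fit.beta))
    assert abs(fit.beta.sum() - single.beta[0]) < 1e-2


def test_cox_requires_events():
    sv = SurvivalData(["a", "b", "c"], [1.0, 2.0, 3.0], [0, 0, 0])
    with pytest.raises(FitError):
        fit_cox(np.ones((3, 1)), sv)


# ---------------------------------------------------------------------------
# prognostic index and c-index


def test_prognostic_index_is_dot_product(rng):
    X = pd.DataFrame(rng.standard_normal((7, 3)), columns=list("abc"))
    sv = random_survival(rng, 7)
    fit = fit_cox(X, sv)
    pi = prognostic_index(fit, X)
    assert np.allclose(pi.to_numpy(), X.to_numpy() @ fit.beta)
    with pytest.raises(KeyError):
        prognostic_index(fit, X[["a", "b"]])


def test_cindex_perfect_and_tied():
    sv = SurvivalData(list("abcd"), [4.0, 3.0, 2.0, 1.0], [1, 1, 1, 1])
    assert concordance_index([1.0, 2.0, 3.0, 4.0], sv) == 1.0
    assert concordance_index([5.0, 5.0, 5.0, 5.0], sv) == 0.5


@pytest.mark.parametrize("seed", range(30))
def test_cindex_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    sv = random_survival(rng, n)
    pi = np.round(rng.standard_normal(n), 1)  # rounded to create index ties
    assert np.isclose(concordance_index(pi, sv), cindex_bruteforce(pi, sv.time, sv.event))


def test_cindex_antisymmetric_without_ties(rng):
    sv = random_survival(rng, 40)
    pi = rng.standard_normal(40)
    assert np.isclose(concordance_index(pi, sv), 1.0 - concordance_index(-pi, sv))


def test_cindex_all_censored_raises():
    sv = SurvivalData(list("ab"), [1.0, 2.0], [0, 0])
    with pytest.raises(FitError):
        concordance_index([0.1, 0.2], sv)


# ---------------------------------------------------------------------------
# log-rank median split


def test_logrank_identical_groups_is_null():
    time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    sv = SurvivalData([f"p{i}" for i in range(8)], time, event)
    pi = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
    chi2, p, tier = logrank_median_split(pi, sv)
    assert chi2 < 1e-9 and p > 0.999 and tier == "none"


def test_logrank_matches_riskset_oracle(rng):
    n = 10
    sv = random_survival(rng, n)
    pi = rng.standard_normal(n)
    chi2, _, _ = logrank_median_split(pi, sv)
    group = pi > np.median(pi)
    assert np.isclose(chi2, logrank_riskset(sv.time, sv.event, group), rtol=1e-10)


def test_logrank_invariant_to_group_relabeling(rng):
    n = 30
    sv = random_survival(rng, n)
    pi = rng.standard_normal(n)
    chi2a, _, _ = logrank_median_split(pi, sv)
    # negating the index swaps group labels (no ties at the median here)
    chi2b, _, _ = logrank_median_split(-pi, sv)
    assert np.isclose(chi2a, chi2b, rtol=1e-8)


@pytest.mark.parametrize(
    "p,tier", [(0.2, "none"), (0.04, "a"), (0.009, "b"), (0.0005, "c")]
)
def test_significance_tiers(p, tier):
    assert significance_tier(p) == tier


# ---------------------------------------------------------------------------
# Cohen's kappa


def test_kappa_known_values():
    assert cohen_kappa([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
    assert cohen_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == -1.0
    # 2x2 table: 4 both-high, 1, 1, 4 both-low -> po=0.8, pe=0.5, kappa=0.6
    a = [1] * 5 + [0] * 5
    b = [1] * 4 + [0] + [1] + [0] * 4
    assert np.isclose(cohen_kappa(a, b), 0.6)


def test_kappa_undefined_for_constant_raters():
    assert np.isnan(cohen_kappa([1, 1, 1], [1, 1, 1]))


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=40))
@settings(deadline=None, max_examples=50)
def test_kappa_symmetric_and_matches_formula(pairs):
    a = np.array([int(p[0]) for p in pairs])
    b = np.array([int(p[1]) for p in pairs])
    k1, k2 = cohen_kappa(a, b), cohen_kappa(b, a)
    po = np.mean(a == b)
    pe = a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean())
    if pe >= 1.0:
        assert np.isnan(k1) and np.isnan(k2)
    else:
        assert np.isclose(k1, (po - pe) / (1 - pe)) and np.isclose(k1, k2)


def test_kappa_agrees_with_sklearn(rng):
    from sklearn.metrics import cohen_kappa_score

    a, b = (rng.random(200) < 0.5).astype(int), (rng.random(200) < 0.4).astype(int)
    assert np.isclose(cohen_kappa(a, b), cohen_kappa_score(a, b))


# ---------------------------------------------------------------------------
# resampling protocol


def test_stratified_split_exact_thirds():
    sv = SurvivalData(
        [f"p{i}" for i in range(120)],
        np.arange(1.0, 121.0),
        np.array([0] * 90 + [1] * 30),
    )
    train, test = stratified_split(sv, seed=7)
    assert len(train) == 80 and len(test) == 40
    train_events = sum(sv.event[sv.patient_ids.index(p)] for p in train)
    assert train_events == 20
    assert sorted(train + test) == sorted(sv.patient_ids)
    assert stratified_split(sv, seed=7) == (train, test)
    assert stratified_split(sv, seed=8) != (train, test)


@pytest.mark.parametrize("seed", range(5))
def test_stratified_split_preserves_event_fraction(seed):
    rng = np.random.default_rng(seed)
    sv = random_survival(rng, int(rng.integers(30, 200)))
    train, _ = stratified_split(sv, seed=seed)
    idx = {p: i for i, p in enumerate(sv.patient_ids)}
    frac_train = np.mean([sv.event[idx[p]] for p in train])
    # within one patient of the global event fraction
    assert abs(frac_train * len(train) - sv.event.mean() * len(train)) <= 1.0


def test_stratified_bootstrap_preserves_strata(rng):
    sv = random_survival(rng, 80)
    ids = stratified_bootstrap(sv, seed=3)
    assert len(ids) == 80
    idx = {p: i for i, p in enumerate(sv.patient_ids)}
    assert sum(sv.event[idx[p]] for p in ids) == sv.n_events


def test_bootstrap_distinct_fraction():
    rng = np.random.default_rng(5)
    sv = random_survival(rng, 1000)
    distinct = [
        len(set(stratified_bootstrap(sv, seed=s))) / 1000 for s in range(20)
    ]
    assert abs(np.mean(distinct) - (1 - np.exp(-1))) < 0.02


def test_bootstrap_cindex_perfect_predictor(rng):
    n = 60
    x = np.linspace(1, 2, n)
    time = 100.0 / x + rng.uniform(0, 1e-6, n)  # deterministic inverse ranking
    sv = SurvivalData([f"p{i}" for i in range(n)], time, np.ones(n, dtype=int))
    for B in (1, 5):
        assert bootstrap_cindex(x[:, None], sv, B=B, seed=1) == 1.0


def test_bootstrap_cindex_variance_shrinks_with_B():
    rng = np.random.default_rng(9)
    n = 50
    x = rng.standard_normal(n)
    sv = random_survival(rng, n, censor_frac=0.2)
    est = {
        B: [bootstrap_cindex(x[:, None], sv, B=B, seed=s) for s in range(15)]
        for B in (5, 50)
    }
    assert np.var(est[50]) < np.var(est[5])
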