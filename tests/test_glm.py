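"""Cloglog link, ML fitting, sandwich covariance, recentring, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from fragsurv import (
    CloglogHazardGLM,
    HazardModelSpec,
    Term,
    cloglog,
    estimate_lifetable,
    fit_hazard_model,
    inverse_cloglog,
    predict_functions,
)
from fragsurv.glm import SeparationError, SingularDesignError, _loglik_score_info


# -- link functions ---------------------------------------------------------

def test_inverse_cloglog_of_published_intercept_is_080():
    assert round(inverse_cloglog(0.4812), 2) == 0.80


def test_link_closed_forms():
    assert inverse_cloglog(0.0) == pytest.approx(1 - np.exp(-1))
    assert cloglog(0.5) == pytest.approx(np.log(np.log(2)))


@pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
def test_cloglog_domain_error(p):
    with pytest.raises(ValueError):
        cloglog(p)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(p=st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_link_round_trip(p):
    assert inverse_cloglog(cloglog(p)) == pytest.approx(p, rel=1e-9)


def test_inverse_link_is_monotone_into_unit_interval():
    eta = np.linspace(-10, 3, 200)  # beyond ~3.6 the hazard saturates to 1.0 in floats
    h = inverse_cloglog(eta)
    assert ((h > 0) & (h < 1)).all() and (np.diff(h) > 0).all()


# -- fitting ----------------------------------------------------------------

def _neg_loglik(x, y):
    def f(beta):
        return -_loglik_score_info(x @ beta, y)[0]
    return f


def test_tiny_instance_matches_derivative_free_optimizer(small_pp):
    """ML estimates on a <=30-row instance agree with Nelder-Mead to 1e-6."""
    rng = np.random.default_rng(0)
    small = small_pp.iloc[rng.choice(len(small_pp), 30, replace=False)].reset_index(drop=True)
    spec = HazardModelSpec(baseline_degree=1, terms=("Manmade",))
    fit = fit_hazard_model(small, spec)
    x, _ = spec.design_matrix(small)
    y = small["EVENT"].to_numpy(dtype=float)
    res = optimize.minimize(
        _neg_loglik(x, y), np.zeros(x.shape[1]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50000},
    )
    assert np.abs(res.x - fit.estimates).max() < 1e-6


def test_fit_matches_statsmodels_glm(small_pp):
    """Independent IRLS implementation (statsmodels) reaches the same optimum."""
    sm = pytest.importorskip("statsmodels.api")
    spec = HazardModelSpec(baseline_degree=2, terms=("Repetition", "Manmade", "Patient"))
    fit = fit_hazard_model(small_pp, spec)
    x, _ = spec.design_matrix(small_pp)
    y = small_pp["EVENT"].to_numpy(dtype=float)
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    res = sm.GLM(y, x, family=fam).fit(tol=1e-12)
    assert np.abs(res.params - fit.estimates).max() < 1e-6
    assert fit.loglik == pytest.approx(res.llf, abs=1e-6)


def test_cluster_robust_covariance_matches_statsmodels(small_pp):
    """Sandwich agrees with statsmodels' cluster covariance up to its extra
    finite-sample factor (within 1%)."""
    sm = pytest.importorskip("statsmodels.api")
    spec = HazardModelSpec(baseline_degree=2, terms=("Manmade", "Patient"))
    fit = fit_hazard_model(small_pp, spec)
    x, _ = spec.design_matrix(small_pp)
    y = small_pp["EVENT"].to_numpy(dtype=float)
    groups, _ = pd.factorize(small_pp["participant_id"])
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    res = sm.GLM(y, x, family=fam).fit(cov_type="cluster", cov_kwds={"groups": groups})
    ours = np.sqrt(np.diag(fit.cov_cluster_robust))
    assert np.allclose(ours, res.bse, rtol=0.01)


def test_saturated_fit_reproduces_empirical_hazards():
    table = pd.DataFrame(
        {"TIME": [1] * 100 + [2] * 20, "EVENT": [1] * 80 + [0] * 20 + [1] * 10 + [0] * 10}
    )
    fit = fit_hazard_model(table, HazardModelSpec(baseline_degree=1))
    pred = fit.predict_functions({"b": {}}, horizon=2)
    assert np.allclose(pred["hazard"], [0.8, 0.5], atol=1e-9)


def test_intercept_recovery_at_large_n():
    """Intercept-only truth eta* = 0.4812 recovered within 0.05 at ~5e4 rows."""
    from fragsurv import SimulationConfig, encode_predictors, expand_to_person_period, simulate_dataset

    cfg = SimulationConfig(
        n_controls=200, include_patient=False,
        true_coefficients={"Intercept": 0.4812}, seed=99,
    )
    pp = expand_to_person_period(encode_predictors(simulate_dataset(cfg)))
    fit = fit_hazard_model(pp, HazardModelSpec(baseline_degree=0))
    assert abs(fit.coef["Intercept"] - 0.4812) < 0.05


def test_rank_deficient_design_names_collinear_columns(small_pp):
    table = small_pp.assign(Manmade2=lambda d: d["Manmade"])
    spec = HazardModelSpec(baseline_degree=1, terms=("Manmade", "Manmade2"))
    with pytest.raises(SingularDesignError, match="Manmade"):
        fit_hazard_model(table, spec)


def test_complete_separation_is_detected():
    table = pd.DataFrame({"TIME": [1] * 40, "EVENT": [1] * 20 + [0] * 20,
                          "A": [1] * 20 + [0] * 20})
    with pytest.raises(SeparationError):
        fit_hazard_model(table, HazardModelSpec(baseline_degree=0, terms=("A",)))


def test_non_binary_event_rejected(small_pp):
    bad = small_pp.copy()
    bad.loc[bad.index[0], "EVENT"] = 2
    with pytest.raises(ValueError):
        fit_hazard_model(bad, HazardModelSpec(baseline_degree=0))


def test_sandwich_equals_model_covariance_for_saturated_row_clusters():
    """With one-row clusters and a saturated model the meat equals the bread,
    leaving only the documented G/(G-1) factor."""
    table = pd.DataFrame(
        {"TIME": [1] * 50 + [2] * 30, "EVENT": [1] * 20 + [0] * 30 + [1] * 10 + [0] * 20}
    )
    fit = fit_hazard_model(table, HazardModelSpec(baseline_degree=1), cluster="row_id")
    n = len(table)
    assert np.allclose(fit.cov_cluster_robust, fit.cov_model * n / (n - 1), rtol=1e-6)


# -- hazard ratios and recentring ------------------------------------------

def test_hazard_ratio_examples(small_pp):
    fit = fit_hazard_model(small_pp, HazardModelSpec(baseline_degree=1, terms=("Manmade",)))
    assert fit.hazard_ratio("Manmade") == pytest.approx(np.exp(fit.coef["Manmade"]))
    with pytest.raises(KeyError):
        fit.hazard_ratio("NotATerm")


@pytest.mark.parametrize("pe, hr", [(0.5968, 1.82), (0.0, 1.0), (-2.4522, 0.09)])
def test_hazard_ratio_is_antilogged_estimate(pe, hr):
    assert round(float(np.exp(pe)), 2) == hr


def test_recentring_preserves_likelihood_and_predictions(small_pp):
    spec = HazardModelSpec(baseline_degree=3, terms=("Manmade", "Manmade*PT"))
    fit = fit_hazard_model(small_pp, spec)
    for c in (3, 5, 9):
        rec = fit.recenter(c)
        assert rec.loglik == fit.loglik
        p0 = fit.predict_functions({"m": {"Manmade": 1}})
        p1 = rec.predict_functions({"m": {"Manmade": 1}})
        assert np.allclose(p0["hazard"], p1["hazard"], atol=1e-8)
        assert np.allclose(p0["survivor"], p1["survivor"], atol=1e-8)
    # recentring to the original centre is the identity
    assert np.allclose(fit.recenter(1).estimates, fit.estimates)


def test_recentring_agrees_with_refit(small_pp):
    spec = HazardModelSpec(baseline_degree=2, terms=("Manmade", "Manmade*PT"))
    fit = fit_hazard_model(small_pp, spec)
    refit = fit_hazard_model(small_pp, spec.with_center(5))
    rec = fit.recenter(5)
    assert np.abs(rec.estimates - refit.estimates).max() < 1e-6
    assert rec.loglik == pytest.approx(refit.loglik, abs=1e-8)


# -- prediction -------------------------------------------------------------

def test_zero_coefficients_give_constant_hazard():
    coefs = {"Intercept": 0.0, "PT": 0.0}
    pred = predict_functions(coefs, {"b": {}}, horizon=10)
    assert np.allclose(pred["hazard"], 1 - np.exp(-1))
    assert np.allclose(pred["survivor"], np.exp(-np.arange(1, 11)))


def test_unknown_condition_covariate_is_an_error():
    with pytest.raises(KeyError):
        predict_functions({"Intercept": 0.0}, {"c": {"Nope": 1}})


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_predicted_survivor_is_monotone_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    coefs = {"Intercept": rng.normal(), "PT": rng.normal(scale=0.5),
             "PT^2": rng.normal(scale=0.1), "A": rng.normal()}
    pred = predict_functions(coefs, {"a": {"A": 1}, "b": {}}, horizon=10)
    for _, g in pred.groupby("condition"):
        s = g["survivor"].to_numpy()
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()


# -- estimator API ----------------------------------------------------------

def test_estimator_follows_sklearn_conventions(small_pp):
    est = CloglogHazardGLM(spec=HazardModelSpec(baseline_degree=1, terms=("Manmade",)))
    params = est.get_params()
    assert "spec" in params and "cluster" in params
    est.fit(small_pp)
    assert est.converged_ and est.coef_.shape == (3,)
    h = est.predict_hazard(small_pp)
    assert ((h > 0) & (h < 1)).all()
    clone_params = CloglogHazardGLM(**params).get_params()
    assert clone_params["cluster"] == params["cluster"]
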