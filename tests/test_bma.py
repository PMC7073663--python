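import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pai_allocate import (
    BMAConfig,
    enumerate_models,
    log_bf_given_g,
    log_marginal_zs,
    log_marginal_zs_quadrature,
    mcmc_bas,
    top_model_table,
)


# --- conditional g-prior Bayes factor -------------------------------------


def test_null_model_bayes_factor_is_exactly_zero():
    assert log_bf_given_g(50, 0, 0.0, 10.0) == 0.0
    assert log_marginal_zs(50, 0, 0.0) == 0.0
    assert log_marginal_zs_quadrature(50, 0, 0.0) == 0.0


def test_uninformative_fit_is_penalized():
    # R^2 = 0 with included predictors: pure dimension penalty, negative
    assert log_bf_given_g(100, 3, 0.0, 20.0) < 0.0


def test_conditional_bf_matches_independent_arithmetic():
    # re-evaluate the two-term expression with the math module only
    n, p, r2, g = 50, 2, 0.3, 50.0
    expected = ((n - 1 - p) / 2) * math.log(1 + g) - ((n - 1) / 2) * math.log(
        1 + g * (1 - r2)
    )
    assert log_bf_given_g(n, p, r2, g) == pytest.approx(expected, abs=1e-12)


@given(
    r2=st.floats(0.01, 0.95),
    g=st.floats(0.1, 1e4),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_conditional_bf_increases_with_fit_quality(r2, g):
    lo = log_bf_given_g(120, 4, r2, g)
    hi = log_bf_given_g(120, 4, min(r2 + 0.02, 0.97), g)
    assert hi > lo


def test_saturated_fit_rejected():
    with pytest.raises(ValueError):
        log_bf_given_g(50, 2, 1.0, 10.0)
    with pytest.raises(ValueError):
        log_marginal_zs(50, 2, 1.0)


# --- ZS-null marginal: Laplace vs quadrature ------------------------------


def test_laplace_agrees_with_quadrature_spotcheck():
    a = log_marginal_zs(100, 3, 0.4, 1.0)
    b = log_marginal_zs_quadrature(100, 3, 0.4, 1.0)
    assert abs(a - b) < 0.05


def test_zs_marginal_monotone_in_r_squared():
    vals = [log_marginal_zs(150, 4, r2) for r2 in (0.0, 0.2, 0.4, 0.6, 0.8)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


# --- enumeration ----------------------------------------------------------


def _toy_data(n=100, p=5, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (X[:, 0] - 0.5 * X[:, 1] if signal else 0.0) + rng.standard_normal(n)
    return X, np.asarray(y)


def test_single_predictor_pip_is_two_model_normalization():
    rng = np.random.default_rng(1)
    n = 80
    x = rng.standard_normal((n, 1))
    y = 0.8 * x[:, 0] + rng.standard_normal(n)
    res = enumerate_models(x, y, BMAConfig())
    # direct two-model computation: pip = BF / (1 + BF)
    xc = x[:, 0] - x[:, 0].mean()
    yc = y - y.mean()
    r2 = float((xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc)))
    bf = math.exp(log_marginal_zs(n, 1, r2))
    assert res.pip.iloc[0] == pytest.approx(bf / (1 + bf), abs=1e-10)


def test_posterior_probabilities_sum_to_one():
    X, y = _toy_data()
    res = enumerate_models(X, y)
    assert res.posterior.sum() == pytest.approx(1.0, abs=1e-10)
    assert ((res.pip >= 0) & (res.pip <= 1)).all()


def test_duplicate_columns_get_symmetric_pips():
    # exactly duplicated predictor: the posterior cannot prefer either copy
    rng = np.random.default_rng(2)
    n = 120
    z = rng.standard_normal(n)
    X = np.column_stack([z, z.copy()])
    y = z + rng.standard_normal(n)
    res = enumerate_models(X, y)
    assert res.pip.iloc[0] == pytest.approx(res.pip.iloc[1], abs=1e-8)


def test_scale_invariance_of_pips():
    X, y = _toy_data(seed=3)
    a = enumerate_models(X, y)
    b = enumerate_models(X, 37.5 * y)
    np.testing.assert_allclose(a.pip.to_numpy(), b.pip.to_numpy(), atol=1e-9)
    np.testing.assert_allclose(a.log_marginals, b.log_marginals, atol=1e-7)


def test_null_data_rarely_promotes_predictors():
    # y independent of X: across replicates most runs keep every pip < 0.5
    hits = 0
    for rep in range(50):
        X, y = _toy_data(n=200, p=8, seed=rep, signal=False)
        res = enumerate_models(X, y)
        hits += bool((res.pip < 0.5).all())
    assert hits >= 35  # a large majority of the 50 replicates


def test_enumeration_rejects_empty_and_oversized_spaces():
    X, y = _toy_data()
    with pytest.raises(ValueError, match="no candidate predictors"):
        enumerate_models(X[:, :0], y)
    with pytest.raises(ValueError, match="enumeration_limit"):
        enumerate_models(np.random.default_rng(0).standard_normal((40, 25)),
                         np.zeros(40), BMAConfig())


def test_beta_binomial_prior_reweights_model_sizes():
    X, y = _toy_data(seed=4)
    uni = enumerate_models(X, y, BMAConfig(model_prior="uniform"))
    bb = enumerate_models(X, y, BMAConfig(model_prior="beta_binomial"))
    assert not np.allclose(uni.posterior, bb.posterior)
    assert bb.posterior.sum() == pytest.approx(1.0, abs=1e-10)


# --- MCMC + BAS sampler ---------------------------------------------------


def test_sampler_is_deterministic_under_fixed_seed():
    X, y = _toy_data(n=150, p=12, seed=5)
    cfg = BMAConfig(seed=99, n_models=600, enumeration_limit=5)
    a = mcmc_bas(X, y, cfg)
    b = mcmc_bas(X, y, cfg)
    np.testing.assert_array_equal(a.gammas, b.gammas)
    np.testing.assert_allclose(a.pip.to_numpy(), b.pip.to_numpy(), atol=0)


def test_sampler_equals_enumeration_when_budget_exhausts_space():
    X, y = _toy_data(n=150, p=8, seed=6)
    enum = enumerate_models(X, y, BMAConfig())
    samp = mcmc_bas(X, y, BMAConfig(seed=0, n_models=1 << 8))
    assert samp.n_models_evaluated == 1 << 8
    np.testing.assert_allclose(enum.pip.to_numpy(), samp.pip.to_numpy(), atol=1e-12)


def test_sampler_budget_floor():
    X, y = _toy_data()
    with pytest.raises(ValueError, match="budget"):
        mcmc_bas(X, y, BMAConfig(n_models=5))


# --- top-model report -----------------------------------------------------


def test_top_model_table_layout():
    X, y = _toy_data(seed=7)
    res = enumerate_models(pd.DataFrame(X, columns=[f"c{j}" for j in range(5)]), y)
    tab = top_model_table(res, K=5)
    assert list(tab["Model"]) == [1, 2, 3, 4, 5]
    assert tab["Bayes Factor"].iloc[0] == 1.0
    assert (tab["Bayes Factor"].diff().dropna() <= 1e-12).all()  # descending
    best_lm = tab["Log Marginal Likelihood"].iloc[0]
    np.testing.assert_allclose(
        tab["Bayes Factor"], np.exp(tab["Log Marginal Likelihood"] - best_lm)
    )
    one = top_model_table(res, K=1)
    assert len(one) == 1
    assert one["Posterior Probability"].iloc[0] == pytest.approx(res.posterior.max())


def test_top_model_table_truncates_with_warning():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((50, 1))
    y = x[:, 0] + rng.standard_normal(50)
    res = enumerate_models(x, y)
    with pytest.warns(UserWarning, match="truncating"):
        tab = top_model_table(res, K=10)
    assert len(tab) == 2
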