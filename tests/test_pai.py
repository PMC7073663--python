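import numpy as np
import pandas as pd
import pytest

from pai_allocate import (
    BMAConfig,
    SelectionRule,
    enumerate_models,
    loo_predictions,
    select_predictors,
    summarize_pai,
)
from pai_allocate.bma import BMAResult
from pai_allocate.pai import PatientPrediction


def _fake_result(pips, top_gamma):
    p = len(pips)
    gammas = np.vstack([top_gamma, np.zeros(p, dtype=int)])
    return BMAResult(
        arm="TAU",
        columns=[f"c{j}" for j in range(p)],
        gammas=gammas.astype(bool),
        log_marginals=np.array([1.0, 0.0]),
        r_squared=np.array([0.5, 0.0]),
        log_prior=np.zeros(2),
        posterior=np.array([0.7, 0.3]),
        pip=pd.Series(pips, index=[f"c{j}" for j in range(p)]),
        method="enumeration",
        n_models_evaluated=2,
    )


def test_highest_posterior_model_takes_top_gamma():
    res = _fake_result([0.9, 0.2, 0.8], [1, 0, 1])
    sel = select_predictors(res, SelectionRule("highest_posterior_model"))
    assert sel.columns == ("c0", "c2")
    assert not sel.null_model


def test_median_probability_model_thresholds_pips():
    res = _fake_result([0.99, 0.51, 0.49], [1, 0, 0])
    sel = select_predictors(res, SelectionRule("median_probability_model"))
    assert sel.columns == ("c0", "c1")  # strictly above 0.5


def test_empty_median_probability_model_falls_back_to_intercept():
    res = _fake_result([0.2, 0.3, 0.1], [1, 0, 0])
    with pytest.warns(UserWarning, match="intercept"):
        sel = select_predictors(res, SelectionRule("median_probability_model"))
    assert sel.columns == ()
    assert sel.null_model


def test_selection_rules_can_disagree_on_real_posterior():
    # two near-collinear informative columns plus a weak third: the top
    # model omits a column whose posterior inclusion mass still exceeds 1/2
    rng = np.random.default_rng(7)
    n = 60
    z = rng.standard_normal(n)
    X = np.column_stack(
        [z + 0.1 * rng.standard_normal(n),
         z + 0.1 * rng.standard_normal(n),
         rng.standard_normal(n)]
    )
    y = z + 0.35 * X[:, 2] + rng.standard_normal(n)
    res = enumerate_models(X, y, BMAConfig(seed=0))
    hpm = set(select_predictors(res, SelectionRule("highest_posterior_model")).columns)
    mpm = set(select_predictors(res, SelectionRule("median_probability_model")).columns)
    assert mpm - hpm  # MPM keeps a pip>0.5 column the top model excludes


# --- leave-one-out predictions --------------------------------------------


def _arm_frames(n, p, seed, beta=None, intercept=0.0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)),
        columns=[f"c{j}" for j in range(p)],
        index=[f"P{seed}{i:03d}" for i in range(n)],
    )
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    y = pd.Series(
        intercept + X.to_numpy() @ beta + noise * rng.standard_normal(n), index=X.index
    )
    return X, y


def test_identical_arms_give_near_zero_pai():
    X, y = _arm_frames(200, 2, seed=1, beta=[1.0, -0.5])
    preds = loo_predictions(
        (X, y), (X, y), ("c0", "c1"), ("c0", "c1"),
        received_arm="TAU", other_arm="BLEND",
    )
    # the factual fit excludes the patient while the counterfactual fit
    # keeps the identical twin row, so the PAI is the leave-one-out
    # perturbation: O(leverage) ~ 1/n, vanishing for a large arm
    assert max(p.pai for p in preds) < 0.3
    assert np.mean([p.pai for p in preds]) < 0.05


def test_lower_factual_prediction_marks_received_arm_optimal():
    X_r, y_r = _arm_frames(25, 1, seed=2, beta=[0.0], intercept=5.0, noise=0.1)
    X_o, y_o = _arm_frames(25, 1, seed=3, beta=[0.0], intercept=15.0, noise=0.1)
    preds = loo_predictions(
        (X_r, y_r), (X_o, y_o), ("c0",), ("c0",),
        received_arm="TAU", other_arm="BLEND",
    )
    assert all(p.optimal_arm == "TAU" for p in preds)
    assert all(p.received_optimal for p in preds)
    assert all(p.pai == abs(p.factual_pred - p.counterfactual_pred) for p in preds)


def test_loo_matches_normal_equations_on_toy_arm():
    # 8-patient arm, 2 predictors: hand-computed refit without each patient
    X_r, y_r = _arm_frames(8, 2, seed=4, beta=[1.0, 2.0], intercept=3.0)
    X_o, y_o = _arm_frames(12, 2, seed=5, beta=[1.0, 2.0], intercept=3.0)
    preds = loo_predictions(
        (X_r, y_r), (X_o, y_o), ("c0", "c1"), ("c0", "c1"),
        received_arm="TAU", other_arm="BLEND",
    )
    D = np.column_stack([np.ones(8), X_r.to_numpy()])
    yv = y_r.to_numpy()
    for i, p in enumerate(preds):
        keep = np.arange(8) != i
        A = D[keep]
        coef = np.linalg.solve(A.T @ A, A.T @ yv[keep])
        assert p.factual_pred == pytest.approx(float(D[i] @ coef), abs=1e-8)


def test_predictions_invariant_to_own_outcome():
    X_r, y_r = _arm_frames(20, 2, seed=6, beta=[1.0, 0.5])
    X_o, y_o = _arm_frames(20, 2, seed=7, beta=[0.5, 1.0])
    base = loo_predictions(
        (X_r, y_r), (X_o, y_o), ("c0", "c1"), ("c0",),
        received_arm="TAU", other_arm="BLEND",
    )
    y_mod = y_r.copy()
    y_mod.iloc[3] += 50.0  # only patient 3's own outcome changes
    mod = loo_predictions(
        (X_r, y_mod), (X_o, y_o), ("c0", "c1"), ("c0",),
        received_arm="TAU", other_arm="BLEND",
    )
    assert mod[3].factual_pred == pytest.approx(base[3].factual_pred, abs=1e-10)
    assert mod[3].counterfactual_pred == pytest.approx(base[3].counterfactual_pred, abs=1e-12)
    # other patients' factual fits DO see the perturbed outcome
    assert mod[4].factual_pred != pytest.approx(base[4].factual_pred, abs=1e-6)


def test_insufficient_fold_size_rejected():
    X_r, y_r = _arm_frames(3, 2, seed=8)
    with pytest.raises(ValueError, match="training rows"):
        loo_predictions(
            (X_r, y_r), (X_r, y_r), ("c0", "c1"), ("c0",),
            received_arm="TAU", other_arm="BLEND",
        )


def test_clipping_flag_bounds_predictions():
    X_r, y_r = _arm_frames(15, 1, seed=9, beta=[0.0], intercept=40.0, noise=0.1)
    y_r = y_r.clip(0, 27)  # observed outcomes must stay on scale
    preds = loo_predictions(
        (X_r, y_r), (X_r, y_r), ("c0",), ("c0",),
        received_arm="TAU", other_arm="BLEND", clip=True,
    )
    assert all(0.0 <= p.factual_pred <= 27.0 for p in preds)


# --- cohort summary -------------------------------------------------------


def _pred(pid, fact, cf, observed, arm="TAU", other="BLEND"):
    optimal = arm if fact <= cf else other
    return PatientPrediction(
        patient_id=pid, received_arm=arm, factual_pred=fact,
        counterfactual_pred=cf, optimal_arm=optimal, pai=abs(fact - cf),
        observed_outcome=observed, received_optimal=optimal == arm,
    )


def test_all_zero_pai_counts_everyone_optimal():
    preds = [_pred(f"P{i}", 10.0, 10.0, 9.0) for i in range(5)]
    s = summarize_pai(preds)
    assert s.mean_pai == 0.0
    assert s.frac_pai_ge_threshold == 0.0
    assert s.n_optimal == 5 and s.n_suboptimal == 0
    assert s.mean_outcome_suboptimal is None


def test_summary_partitions_cohort_and_scores_error():
    preds = [
        _pred("P0", 8.0, 14.0, 9.0),   # optimal, pai 6
        _pred("P1", 12.0, 7.0, 13.0),  # suboptimal, pai 5
        _pred("P2", 10.0, 12.0, 11.0),  # optimal, pai 2
    ]
    s = summarize_pai(preds, threshold=5.0)
    assert s.n == s.n_optimal + s.n_suboptimal == 3
    assert s.mean_pai == pytest.approx((6 + 5 + 2) / 3)
    assert s.frac_pai_ge_threshold == pytest.approx(2 / 3)
    assert s.mean_outcome_optimal == pytest.approx(10.0)
    assert s.mean_outcome_suboptimal == pytest.approx(13.0)
    assert s.mean_absolute_error == pytest.approx((1 + 1 + 1) / 3)


def test_summary_invariant_to_patient_order():
    preds = [_pred(f"P{i}", 10.0 + i, 12.0, float(8 + i)) for i in range(6)]
    a = summarize_pai(preds)
    b = summarize_pai(list(reversed(preds)))
    assert a == b
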