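"""Predictor selection, leave-one-out prediction and the PAI summaries.

Given per-arm BMA results, a predictor set is selected once per arm —
either the highest-posterior model (HPM, default) or the
median-probability model (MPM: every column with PIP > 0.5) — and held
fixed. For each patient a *factual* prediction (outcome under the
received arm, from an OLS fit on that arm excluding the patient — the
jackknife) and a *counterfactual* prediction (outcome under the other
arm, from an OLS fit on the entire other arm, which never contains the
patient) are computed. The personalized advantage index (PAI) is the
absolute difference of the two predictions; the arm with the smaller
predicted PHQ-9 is the patient's optimal treatment. Cohort summaries
report the mean PAI, the fraction of patients with a clinically
meaningful PAI (>= 5 PHQ-9 points by default), the observed outcome
means of the optimal- vs. suboptimal-allocated groups, and the mean
absolute factual prediction error ("true error").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bma import BMAResult
from .trial import OUTCOME_MAX, OUTCOME_MIN


@dataclass(frozen=True)
class SelectionRule:
    """Predictor-selection rule: ``highest_posterior_model`` or
    ``median_probability_model`` (PIP > 0.5)."""

    rule: str = "highest_posterior_model"

    def __post_init__(self) -> None:
        if self.rule not in ("highest_posterior_model", "median_probability_model"):
            raise ValueError(f"unknown selection rule {self.rule!r}")


@dataclass(frozen=True)
class SelectedModel:
    """Outcome of predictor selection for one arm."""

    arm: str | None
    rule: str
    columns: tuple[str, ...]
    null_model: bool  # True when the selection is intercept-only
    pips: dict

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "rule": self.rule,
            "columns": list(self.columns),
            "null_model": self.null_model,
            "pips": {k: float(v) for k, v in self.pips.items()},
        }


def select_predictors(result: BMAResult, rule: SelectionRule | None = None) -> SelectedModel:
    """Select the predictor set for one arm from its BMA posterior.

    HPM takes the inclusion vector of the top model; MPM takes every
    column with PIP strictly above 0.5 (an empty MPM falls back to the
    intercept-only model with a warning and an explicit flag).
    """
    rule = rule or SelectionRule()
    if rule.rule == "highest_posterior_model":
        gamma = result.best_gamma()
        cols = tuple(c for c, g in zip(result.columns, gamma) if g)
    else:
        cols = tuple(c for c in result.columns if result.pip[c] > 0.5)
    null_model = len(cols) == 0
    if null_model and rule.rule == "median_probability_model":
        warnings.warn("median-probability model is empty; using intercept only")
    return SelectedModel(
        arm=result.arm,
        rule=rule.rule,
        columns=cols,
        null_model=null_model,
        pips={c: float(result.pip[c]) for c in result.columns},
    )


@dataclass
class PatientPrediction:
    """Factual/counterfactual prediction pair for one patient."""

    patient_id: str
    received_arm: str
    factual_pred: float
    counterfactual_pred: float
    optimal_arm: str
    pai: float
    observed_outcome: float
    received_optimal: bool

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "received_arm": self.received_arm,
            "factual_pred": self.factual_pred,
            "counterfactual_pred": self.counterfactual_pred,
            "optimal_arm": self.optimal_arm,
            "pai": self.pai,
            "observed_outcome": self.observed_outcome,
            "received_optimal": self.received_optimal,
        }


def _design(X: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    mat = X[list(columns)].to_numpy(dtype=np.float64) if columns else np.empty((len(X), 0))
    return np.column_stack([np.ones(len(X)), mat])


def _ols_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, context: str
) -> np.ndarray:
    """OLS prediction; constant columns are dropped for the fold and a
    singular design falls back to the minimum-norm solution."""
    keep = [0] + [
        j for j in range(1, Xtr.shape[1]) if np.ptp(Xtr[:, j]) > 0
    ]
    if len(keep) < Xtr.shape[1]:
        warnings.warn(f"{context}: constant predictor column dropped for this fold")
    A = Xtr[:, keep]
    coef, _, rank, _ = np.linalg.lstsq(A, ytr, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(f"{context}: singular design; minimum-norm solution used")
    return Xte[:, keep] @ coef


def loo_predictions(
    arm_data: tuple[pd.DataFrame, pd.Series],
    other_arm_data: tuple[pd.DataFrame, pd.Series],
    predictors_received: Sequence[str],
    predictors_other: Sequence[str],
    received_arm: str,
    other_arm: str,
    clip: bool = False,
) -> list[PatientPrediction]:
    """Leave-one-out factual and counterfactual predictions for one arm.

    ``arm_data``/``other_arm_data`` are (design frame indexed by patient
    id, observed outcomes) for the received and the other arm. Both
    predictor sets must have been fixed in advance (selection is not
    redone per fold). Predictions are raw linear predictors — not
    clipped to the 0-27 scale unless ``clip=True``.
    """
    X_r, y_r = arm_data
    X_o, y_o = other_arm_data
    n_r = len(X_r)
    if n_r - 1 <= len(predictors_received):
        raise ValueError("each fold needs more training rows than predictors + 1")
    if len(X_o) <= len(predictors_other):
        raise ValueError("other arm needs more rows than predictors + 1")

    D_r = _design(X_r, predictors_received)
    y_rv = np.asarray(y_r, dtype=np.float64)

    # the counterfactual model never contains the target patient: fit once
    D_o = _design(X_o, predictors_other)
    D_r_on_other = _design(X_r, predictors_other)
    cf_pred = _ols_predict(
        D_o, np.asarray(y_o, dtype=np.float64), D_r_on_other, f"{other_arm} model"
    )

    preds: list[PatientPrediction] = []
    ids = list(X_r.index.astype(str))
    for i in range(n_r):
        rows = np.ones(n_r, dtype=bool)
        rows[i] = False
        fact = float(
            _ols_predict(D_r[rows], y_rv[rows], D_r[i : i + 1], f"fold {ids[i]}")[0]
        )
        cf = float(cf_pred[i])
        if clip:
            fact = float(np.clip(fact, OUTCOME_MIN, OUTCOME_MAX))
            cf = float(np.clip(cf, OUTCOME_MIN, OUTCOME_MAX))
        optimal = received_arm if fact <= cf else other_arm
        preds.append(
            PatientPrediction(
                patient_id=ids[i],
                received_arm=received_arm,
                factual_pred=fact,
                counterfactual_pred=cf,
                optimal_arm=optimal,
                pai=abs(fact - cf),
                observed_outcome=float(y_rv[i]),
                received_optimal=optimal == received_arm,
            )
        )
    return preds


@dataclass
class PAISummary:
    """Cohort-level PAI summary.

    ``mean_pai`` is in PHQ-9 points and reads: under model-optimal
    allocation the 12-week score would be that many points lower than
    under suboptimal allocation. ``mean_absolute_error`` is the mean
    |factual prediction - observed score| ("true error"). Patients with
    a zero PAI (tie) count as having received their optimal treatment.
    """

    n: int
    mean_pai: float
    threshold: float
    frac_pai_ge_threshold: float
    n_optimal: int
    n_suboptimal: int
    mean_outcome_optimal: float
    mean_outcome_suboptimal: float | None
    mean_absolute_error: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_pai": self.mean_pai,
            "threshold": self.threshold,
            "frac_pai_ge_threshold": self.frac_pai_ge_threshold,
            "n_optimal": self.n_optimal,
            "n_suboptimal": self.n_suboptimal,
            "mean_outcome_optimal": self.mean_outcome_optimal,
            "mean_outcome_suboptimal": self.mean_outcome_suboptimal,
            "mean_absolute_error": self.mean_absolute_error,
        }


def summarize_pai(
    preds: Sequence[PatientPrediction], threshold: float = 5.0
) -> PAISummary:
    """Aggregate per-patient predictions into the cohort summary."""
    if not preds:
        raise ValueError("no predictions to summarize")
    pai = np.array([p.pai for p in preds])
    observed = np.array([p.observed_outcome for p in preds])
    fact = np.array([p.factual_pred for p in preds])
    opt = np.array([p.received_optimal for p in preds])
    n_opt = int(opt.sum())
    n_sub = len(preds) - n_opt
    return PAISummary(
        n=len(preds),
        mean_pai=float(pai.mean()),
        threshold=float(threshold),
        frac_pai_ge_threshold=float((pai >= threshold).mean()),
        n_optimal=n_opt,
        n_suboptimal=n_sub,
        mean_outcome_optimal=float(observed[opt].mean()) if n_opt else float("nan"),
        mean_outcome_suboptimal=float(observed[~opt].mean()) if n_sub else None,
        mean_absolute_error=float(np.abs(fact - observed).mean()),
    )
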