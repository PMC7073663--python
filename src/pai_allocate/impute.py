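"""Iterative random-forest imputation of mixed-type baseline covariates.

Implements the missForest procedure: missing cells are initialized with
the column mean (continuous/count) or mode (binary/nominal); variables
are then visited in ascending order of missingness, and for each a random
forest is trained on the rows where that variable was originally observed
(all other covariates, in their current imputed state, as features) and
used to predict the originally missing cells. Sweeps repeat until the
difference between successive imputed matrices increases for both the
continuous part (normalized squared difference) and the categorical part
(disagreement proportion), at which point the previous iterate is
returned, or until ``max_iterations``.

Only baseline covariates are imputed; the outcome never enters the
imputation model set (outcome missingness is handled upstream by the
completer filter). The treatment-arm label is included as a predictor
feature by default since imputation runs on the pooled sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .trial import ARM_COL, ARM_TAU, TrialTable, VariableSpec

_NUMERIC_KINDS = ("continuous", "count")


@dataclass(frozen=True)
class ImputeConfig:
    """Settings for :func:`missforest_impute`.

    ``n_trees`` is the forest size per variable fit (canonical default
    100); ``variable_order`` is ``ascending_missingness`` (default) or
    ``as_given``; ``use_arm_feature`` controls whether the randomization
    arm is offered to the forests as a predictor.
    """

    max_iterations: int = 10
    n_trees: int = 100
    seed: int = 0
    variable_order: str = "ascending_missingness"
    use_arm_feature: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.variable_order not in ("ascending_missingness", "as_given"):
            raise ValueError("variable_order must be ascending_missingness or as_given")

    def to_dict(self) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "variable_order": self.variable_order,
            "use_arm_feature": self.use_arm_feature,
        }


def mask_mcar(
    table: TrialTable, rate: float, seed: int
) -> tuple[TrialTable, pd.DataFrame]:
    """Mask covariate cells completely at random with probability ``rate``.

    Test harness for imputation quality: returns the masked table and a
    boolean frame marking the newly masked cells (original values stay in
    the input table for scoring).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    mask = pd.DataFrame(False, index=out.data.index, columns=table.covariate_names)
    for name in table.covariate_names:
        hit = rng.random(len(out.data)) < rate
        mask[name] = hit
        col = out.data[name].to_numpy(dtype=object, copy=True)
        col[hit] = np.nan
        if table.spec_for(name).kind != "nominal":
            out.data[name] = pd.to_numeric(pd.Series(col), errors="coerce").to_numpy()
        else:
            out.data[name] = col
    return out, mask


def _feature_frame(
    df: pd.DataFrame, schema: tuple[VariableSpec, ...], exclude: str, use_arm: bool
) -> np.ndarray:
    """Numeric feature matrix from the current imputed state (one-hot for
    nominals, arm as 0/1)."""
    blocks: list[np.ndarray] = []
    for s in schema:
        if s.name == exclude:
            continue
        if s.kind == "nominal":
            vals = df[s.name].to_numpy()
            for lev in sorted(s.levels)[1:]:
                blocks.append((vals == lev).astype(np.float64))
        else:
            blocks.append(df[s.name].to_numpy(dtype=np.float64))
    if use_arm:
        blocks.append((df[ARM_COL].to_numpy() == ARM_TAU).astype(np.float64))
    return np.column_stack(blocks)


def _differences(
    new: pd.DataFrame, old: pd.DataFrame, schema: tuple[VariableSpec, ...]
) -> tuple[float | None, float | None]:
    """Stopping-rule distance between successive imputed matrices:
    sum((new-old)^2)/sum(new^2) over numeric cells; disagreement
    proportion over categorical cells."""
    num_num = num_den = 0.0
    cat_mismatch = cat_total = 0
    for s in schema:
        if s.kind in _NUMERIC_KINDS:
            a = new[s.name].to_numpy(dtype=np.float64)
            b = old[s.name].to_numpy(dtype=np.float64)
            num_num += float(np.sum((a - b) ** 2))
            num_den += float(np.sum(a**2))
        else:
            a = new[s.name].to_numpy()
            b = old[s.name].to_numpy()
            cat_mismatch += int(np.sum(a != b))
            cat_total += len(a)
    d_num = (num_num / num_den) if num_den > 0 else (None if num_num == 0 and num_den == 0 else 0.0)
    has_numeric = any(s.kind in _NUMERIC_KINDS for s in schema)
    d_cat = (cat_mismatch / cat_total) if cat_total else None
    return (d_num if has_numeric else None, d_cat)


def missforest_impute(
    table: TrialTable, config: ImputeConfig | None = None
) -> tuple[TrialTable, dict]:
    """Fill all missing covariate cells; observed cells are never altered.

    Returns the imputed table and a diagnostics dict (iterations run,
    per-iteration difference measures, constant-column warnings). Raises
    ``ValueError`` for a covariate with zero observed values.
    """
    config = config or ImputeConfig()
    out = table.copy()
    df = out.data
    schema = out.schema
    na_mask = {name: df[name].isna().to_numpy() for name in out.covariate_names}
    n_missing = {name: int(m.sum()) for name, m in na_mask.items()}

    diagnostics: dict = {
        "config": config.to_dict(),
        "n_missing_per_variable": dict(sorted(n_missing.items())),
        "iterations": 0,
        "differences": [],
        "warnings": [],
    }
    if all(v == 0 for v in n_missing.values()):
        return out, diagnostics

    constant: dict[str, object] = {}
    for s in schema:
        obs = df[s.name][~na_mask[s.name]]
        if len(obs) == 0:
            raise ValueError(f"covariate {s.name!r} has no observed values; cannot train")
        if obs.nunique(dropna=True) == 1 and n_missing[s.name] > 0:
            constant[s.name] = obs.iloc[0]
            warnings.warn(f"covariate {s.name!r} observed as constant; imputing the constant")
            diagnostics["warnings"].append(f"constant column {s.name}")

    # mean/mode initialization
    for s in schema:
        m = na_mask[s.name]
        if not m.any():
            continue
        obs = df[s.name][~m]
        if s.kind in _NUMERIC_KINDS:
            fill = float(obs.mean())
            if s.kind == "count":
                fill = float(np.rint(fill))
            vals = df[s.name].to_numpy(dtype=np.float64, copy=True)
            vals[m] = fill
            df[s.name] = vals
        else:
            fill = obs.mode().iloc[0]
            vals = df[s.name].to_numpy(dtype=object, copy=True)
            vals[m] = fill
            df[s.name] = vals

    to_impute = [s for s in schema if n_missing[s.name] > 0 and s.name not in constant]
    for name, value in constant.items():
        vals = df[name].to_numpy(dtype=object, copy=True)
        vals[na_mask[name]] = value
        df[name] = vals if table.spec_for(name).kind == "nominal" else vals.astype(np.float64)
    if config.variable_order == "ascending_missingness":
        to_impute.sort(key=lambda s: (n_missing[s.name], s.name))
    if not to_impute:  # everything missing sat in constant columns
        out.data = df
        out.validate()
        return out, diagnostics

    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.max_iterations * max(len(to_impute), 1)
    )

    prev = df[out.covariate_names].copy()
    best = prev.copy()
    last_d: tuple[float | None, float | None] | None = None
    for it in range(config.max_iterations):
        for j, s in enumerate(to_impute):
            m = na_mask[s.name]
            feats = _feature_frame(df, schema, s.name, config.use_arm_feature)
            seed = int(seeds[it * len(to_impute) + j] % (2**31))
            if s.kind in _NUMERIC_KINDS:
                model = RandomForestRegressor(
                    n_estimators=config.n_trees, random_state=seed, n_jobs=1
                )
                model.fit(feats[~m], df[s.name].to_numpy(dtype=np.float64)[~m])
                pred = model.predict(feats[m])
                if s.kind == "count":
                    pred = np.maximum(np.rint(pred), 0.0)
                vals = df[s.name].to_numpy(dtype=np.float64, copy=True)
                vals[m] = pred
                df[s.name] = vals
            else:
                model = RandomForestClassifier(
                    n_estimators=config.n_trees, random_state=seed, n_jobs=1
                )
                target = df[s.name].astype(str).to_numpy()
                model.fit(feats[~m], target[~m])
                pred = model.predict(feats[m])
                if s.kind == "binary":
                    vals = df[s.name].to_numpy(dtype=np.float64, copy=True)
                    vals[m] = pred.astype(np.float64)
                    df[s.name] = vals
                else:
                    vals = df[s.name].to_numpy(dtype=object, copy=True)
                    vals[m] = pred
                    df[s.name] = vals
        current = df[out.covariate_names].copy()
        d = _differences(current, prev, tuple(to_impute) or schema)
        diagnostics["differences"].append({"continuous": d[0], "categorical": d[1]})
        diagnostics["iterations"] = it + 1
        if last_d is not None:
            worse_num = d[0] is None or last_d[0] is None or d[0] > last_d[0]
            worse_cat = d[1] is None or last_d[1] is None or d[1] > last_d[1]
            if worse_num and worse_cat:
                # stopping rule fired: keep the previous iterate
                df[out.covariate_names] = best
                diagnostics["stopped_early"] = True
                break
        best = current
        prev = current
        last_d = d
    else:
        diagnostics["stopped_early"] = False

    out.data = df
    out.validate()
    return out, diagnostics
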