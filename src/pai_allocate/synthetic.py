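"""Synthetic two-arm RCT generator with known per-patient ground truth.

Emulates a secondary-care depression trial comparing face-to-face
treatment as usual (TAU) against blended treatment: block randomization
at a 1:1 ratio with blocks of 8-14 allocations, a battery of mixed-type
baseline covariates (sociodemographics, symptomatology and quality of
life, healthcare utilization, patient expectancy), an integer PHQ-9
outcome at 12 weeks on the 0-27 scale, per-covariate missingness, and a
small completer-dropout rate in the outcome.

Each arm has its own linear outcome model over the encoded design
columns. Coefficients shared by the two arms are *prognostic* (predict
outcome regardless of arm); coefficients that differ between arms are
*prescriptive* (predict differential response), and their per-patient
contrast is the ground-truth personalized advantage index (PAI).

Covariates are drawn through a one-factor Gaussian copula: each variable
may load on a shared latent severity factor while keeping exactly its
configured marginal distribution, which gives the correlated baseline
battery seen in real symptom data (loading 0 = independent).

The ground truth (expected outcome under both arms, before noise,
clipping and rounding) is recorded for every patient, so downstream
estimators can be scored against what the generator actually encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .preprocess import design_columns, encode
from .trial import (
    ARM_BLEND,
    ARM_TAU,
    ARM_COL,
    ID_COL,
    OUTCOME_COL,
    OUTCOME_MAX,
    OUTCOME_MIN,
    TrialTable,
    VariableSpec,
    make_table,
    read_sidecar,
)

PRESETS = ("null", "prognostic_only", "prescriptive", "ecompared_like")


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic trial scenario.

    ``beta_tau``/``beta_blend`` map encoded design-column names (see
    :func:`pai_allocate.preprocess.design_columns`) to outcome points per
    covariate unit; unspecified columns have coefficient zero.
    ``miss_rates`` maps covariate names to MCAR missingness fractions in
    [0, 0.5) — below the 50% screening rule unless deliberately set
    higher. ``block_sizes`` are the even block lengths used for 1:1
    block randomization.
    """

    n_patients: int
    covariate_schema: tuple[VariableSpec, ...]
    beta_tau: Mapping[str, float]
    beta_blend: Mapping[str, float]
    intercept_tau: float
    intercept_blend: float
    noise_sd: float
    miss_rates: Mapping[str, float] = field(default_factory=dict)
    outcome_dropout_rate: float = 0.0
    block_sizes: tuple[int, ...] = (8, 10, 12, 14)
    seed: int = 0
    missing_mechanism: str = "mcar"  # "mcar" or "mar"
    mar_driver: str | None = None  # covariate steering MAR missingness
    mar_slope: float = 1.0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        names = [s.name for s in self.covariate_schema]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        cols = {m.column for m in design_columns(self.covariate_schema)}
        for label, beta in (("beta_tau", self.beta_tau), ("beta_blend", self.beta_blend)):
            unknown = set(beta) - cols
            if unknown:
                raise ConfigurationError(
                    f"{label} refers to unknown design column(s): {sorted(unknown)}"
                )
        unknown_miss = set(self.miss_rates) - set(names)
        if unknown_miss:
            raise ConfigurationError(
                f"miss_rates refers to unknown covariate(s): {sorted(unknown_miss)}"
            )
        for name, rate in self.miss_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"miss rate for {name!r} outside [0, 1)")
        if not 0.0 <= self.outcome_dropout_rate <= 0.1:
            raise ConfigurationError("outcome_dropout_rate outside [0, 0.1]")
        for b in self.block_sizes:
            if b % 2 or not 2 <= b:
                raise ConfigurationError("block sizes must be positive even integers")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ConfigurationError("missing_mechanism must be 'mcar' or 'mar'")
        if self.missing_mechanism == "mar" and self.mar_driver is None:
            raise ConfigurationError("mar mechanism needs a mar_driver covariate")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "covariate_schema": [s.to_dict() for s in self.covariate_schema],
            "beta_tau": dict(self.beta_tau),
            "beta_blend": dict(self.beta_blend),
            "intercept_tau": self.intercept_tau,
            "intercept_blend": self.intercept_blend,
            "noise_sd": self.noise_sd,
            "miss_rates": dict(self.miss_rates),
            "outcome_dropout_rate": self.outcome_dropout_rate,
            "block_sizes": list(self.block_sizes),
            "seed": self.seed,
            "missing_mechanism": self.missing_mechanism,
            "mar_driver": self.mar_driver,
            "mar_slope": self.mar_slope,
        }


@dataclass
class SyntheticTruth:
    """Ground truth per patient: expected outcome under both arms.

    ``mu_tau``/``mu_blend`` are the noiseless, unclipped linear
    predictors; ``true_optimal`` is the arm with the smaller expected
    PHQ-9 ("either" for exact ties); ``true_pai`` = |mu_tau - mu_blend|.
    """

    frame: pd.DataFrame  # patient_id, mu_tau, mu_blend, true_optimal, true_pai

    @property
    def mean_true_pai(self) -> float:
        return float(self.frame["true_pai"].mean())

    def to_records(self) -> list[dict]:
        return self.frame.to_dict(orient="records")


def _draw_block_sizes(n: int, block_sizes: Sequence[int], rng: np.random.Generator) -> list[int]:
    sizes: list[int] = []
    remaining = n
    while remaining >= min(block_sizes):
        options = [b for b in block_sizes if b <= remaining]
        sizes.append(int(rng.choice(options)))
        remaining -= sizes[-1]
    if remaining:
        sizes.append(remaining)  # final pad block, possibly smaller/odd
    return sizes


def _block_randomize(n: int, block_sizes: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """1:1 block randomization; an odd final block gets its extra patient
    assigned to a random arm."""
    arms: list[str] = []
    for size in _draw_block_sizes(n, block_sizes, rng):
        half = size // 2
        block = [ARM_TAU] * half + [ARM_BLEND] * half
        if size % 2:
            block.append(ARM_TAU if rng.random() < 0.5 else ARM_BLEND)
        rng.shuffle(block)
        arms.extend(block)
    return np.asarray(arms[:n], dtype=object)


def _draw_covariate(
    spec: VariableSpec, factor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One covariate via the Gaussian copula: latent score = loading*factor
    + sqrt(1-loading^2)*noise, mapped through the marginal's quantile."""
    n = len(factor)
    rho = spec.loading
    z = rng.standard_normal(n)
    s = rho * factor + np.sqrt(1.0 - rho * rho) * z
    p = spec.params
    if spec.kind == "continuous":
        return p.get("mean", 0.0) + p.get("sd", 1.0) * s
    u = ndtr(s)
    if spec.kind == "count":
        lam = p.get("lam", 1.0)
        # cap the uniform to dodge the infinite Poisson quantile at u = 1
        return stats.poisson.ppf(np.minimum(u, 1.0 - 1e-12), lam).astype(np.float64)
    if spec.kind == "binary":
        return (u < p.get("p", 0.5)).astype(np.float64)
    probs = np.asarray(p.get("probs", [1.0 / len(spec.levels)] * len(spec.levels)), dtype=float)
    probs = probs / probs.sum()
    idx = np.searchsorted(np.cumsum(probs), u, side="right")
    idx = np.minimum(idx, len(spec.levels) - 1)
    levels = np.asarray(spec.levels, dtype=object)
    return levels[idx]


def _beta_vector(beta: Mapping[str, float], columns: Sequence[str]) -> np.ndarray:
    return np.asarray([float(beta.get(c, 0.0)) for c in columns])


def generate_trial(config: ScenarioConfig) -> tuple[TrialTable, SyntheticTruth]:
    """Generate one trial table and its ground truth.

    The truth record is computed from the noiseless linear predictors
    *before* Gaussian noise, clipping to 0-27 and integer rounding are
    applied to the observed outcome, and before any missingness is
    injected — so the truth is invariant to the missingness mask.
    All randomness flows from ``config.seed`` through one generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    arms = _block_randomize(n, config.block_sizes, rng)

    factor = rng.standard_normal(n)
    df = pd.DataFrame({ID_COL: [f"P{i:04d}" for i in range(1, n + 1)], ARM_COL: arms})
    for spec in config.covariate_schema:
        df[spec.name] = _draw_covariate(spec, factor, rng)

    # truth from the complete (pre-missingness) covariates
    full = make_table(df.assign(**{OUTCOME_COL: np.zeros(n)}), config.covariate_schema)
    coded = encode(full)
    cols = coded.columns
    Xmat = coded.X.to_numpy()
    mu_tau = config.intercept_tau + Xmat @ _beta_vector(config.beta_tau, cols)
    mu_blend = config.intercept_blend + Xmat @ _beta_vector(config.beta_blend, cols)
    optimal = np.where(mu_tau < mu_blend, ARM_TAU, ARM_BLEND).astype(object)
    optimal[mu_tau == mu_blend] = "either"
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                ID_COL: df[ID_COL].to_numpy(),
                "mu_tau": mu_tau,
                "mu_blend": mu_blend,
                "true_optimal": optimal,
                "true_pai": np.abs(mu_tau - mu_blend),
            }
        )
    )

    mu_received = np.where(arms == ARM_TAU, mu_tau, mu_blend)
    y = mu_received + rng.normal(0.0, config.noise_sd, n)
    y = np.clip(np.rint(y), OUTCOME_MIN, OUTCOME_MAX)

    # missingness after truth: MCAR by default, optional MAR in a driver
    if config.missing_mechanism == "mar":
        driver = df[config.mar_driver].to_numpy(dtype=np.float64)
        sd = driver.std()
        zdrv = (driver - driver.mean()) / (sd if sd > 0 else 1.0)
    for spec in config.covariate_schema:
        rate = float(config.miss_rates.get(spec.name, 0.0))
        if rate <= 0.0:
            continue
        if config.missing_mechanism == "mar" and spec.name != config.mar_driver:
            logit = np.log(rate / (1.0 - rate)) + config.mar_slope * zdrv
            pmiss = 1.0 / (1.0 + np.exp(-logit))
        else:
            pmiss = np.full(n, rate)
        mask = rng.random(n) < pmiss
        col = df[spec.name].to_numpy(dtype=object)
        col[mask] = np.nan
        df[spec.name] = col

    if config.outcome_dropout_rate > 0:
        drop = rng.random(n) < config.outcome_dropout_rate
        y = y.astype(np.float64)
        y[drop] = np.nan

    df[OUTCOME_COL] = y
    table = make_table(df, config.covariate_schema)
    return table, truth


# ---------------------------------------------------------------------------
# presets

_CEQ = {"mean": 15.0, "sd": 5.0}


def _basic_schema() -> tuple[VariableSpec, ...]:
    return (
        VariableSpec("phq9_baseline", "continuous", params={"mean": 15.0, "sd": 5.0}, loading=0.6),
        VariableSpec("ceq_expectancy", "continuous", params=_CEQ, loading=-0.3),
        VariableSpec("eq5d", "continuous", params={"mean": 0.55, "sd": 0.2}, loading=-0.5),
        VariableSpec("age", "continuous", params={"mean": 41.0, "sd": 13.7}),
        VariableSpec("female", "binary", params={"p": 0.68}),
        VariableSpec("psychiatrist_visits", "count", params={"lam": 2.0}, loading=0.3),
    )


def _null_config(seed: int) -> ScenarioConfig:
    # no prescriptive contrasts: both arms share one prognostic model
    beta = {"phq9_baseline": 0.6, "ceq_expectancy": -0.3}
    return ScenarioConfig(
        n_patients=200,
        covariate_schema=_basic_schema(),
        beta_tau=beta,
        beta_blend=dict(beta),
        intercept_tau=6.0,
        intercept_blend=6.0,
        noise_sd=4.0,
        seed=seed,
    )


def _prognostic_only_config(seed: int) -> ScenarioConfig:
    beta = {
        "phq9_baseline": 0.6,
        "ceq_expectancy": -0.3,
        "eq5d": -4.0,
        "psychiatrist_visits": 0.5,
    }
    return ScenarioConfig(
        n_patients=250,
        covariate_schema=_basic_schema(),
        beta_tau=beta,
        beta_blend=dict(beta),
        intercept_tau=8.0,
        intercept_blend=8.0,
        noise_sd=4.0,
        seed=seed,
    )


def _prescriptive_config(seed: int) -> ScenarioConfig:
    # one binary marker with opposite-signed arm-specific effects (+4 / -4)
    schema = (
        VariableSpec("phq9_baseline", "continuous", params={"mean": 15.0, "sd": 5.0}, loading=0.6),
        VariableSpec("benefit_marker", "binary", params={"p": 0.5}),
        VariableSpec("age", "continuous", params={"mean": 41.0, "sd": 13.7}),
        VariableSpec("female", "binary", params={"p": 0.68}),
    )
    return ScenarioConfig(
        n_patients=500,
        covariate_schema=schema,
        beta_tau={"phq9_baseline": 0.6, "benefit_marker": 4.0},
        beta_blend={"phq9_baseline": 0.6, "benefit_marker": -4.0},
        intercept_tau=4.0,
        intercept_blend=3.0,
        noise_sd=4.0,
        seed=seed,
    )


def _ecompared_like_config(seed: int) -> ScenarioConfig:
    """28 candidate baseline predictors mirroring a secondary-care blended
    treatment trial: sociodemographics, symptomatology/quality of life,
    healthcare utilization (12 utilization items) and patient expectancy,
    with per-item missingness spanning 2-41% and n = 251."""
    ticp_items = [
        ("ticp_gp_visits", 1.8, 0.02),
        ("ticp_psychologist_visits", 1.2, 0.05),
        ("ticp_psychotherapist_visits", 1.0, 0.08),
        ("ticp_psychiatrist_visits", 1.5, 0.12),
        ("ticp_ambulatory_mh_visits", 0.8, 0.15),
        ("ticp_alcohol_drug_clinic", 0.2, 0.18),
        ("ticp_selfhelp_groups", 0.4, 0.22),
        ("ticp_day_regular_hospital", 0.5, 0.26),
        ("ticp_day_psychiatric_hospital", 0.6, 0.30),
        ("ticp_outpatient_psychotherapy_days", 1.0, 0.34),
        ("ticp_regular_admissions", 0.3, 0.38),
        ("ticp_psychiatric_admissions", 0.2, 0.408),
    ]
    schema: list[VariableSpec] = [
        VariableSpec("age", "continuous", params={"mean": 41.0, "sd": 13.7}),
        VariableSpec("female", "binary", params={"p": 0.682}),
        VariableSpec(
            "marital_status",
            "nominal",
            levels=("single", "married", "cohabiting", "divorced", "widowed"),
            params={"probs": [0.33, 0.32, 0.21, 0.13, 0.01]},
        ),
        VariableSpec("education_years", "count", params={"lam": 12.0}),
        VariableSpec(
            "country",
            "nominal",
            levels=("Netherlands", "France", "Switzerland", "Denmark"),
            params={"probs": [0.339, 0.322, 0.18, 0.159]},
        ),
        VariableSpec("recurrent_depression", "binary", params={"p": 0.56}, loading=0.2),
        VariableSpec("therapy_preference", "binary", params={"p": 0.5}),
        VariableSpec("dysthymia", "binary", params={"p": 0.07}, loading=0.2),
        VariableSpec("melancholic_episode", "binary", params={"p": 0.40}, loading=0.3),
        VariableSpec("comorbid_anxiety", "binary", params={"p": 0.54}, loading=0.3),
        VariableSpec("antidepressants", "binary", params={"p": 0.51}, loading=0.2),
        VariableSpec("prior_psychotherapy", "binary", params={"p": 0.5}),
        VariableSpec("phq9_baseline", "count", params={"lam": 16.0}, loading=0.6),
        VariableSpec("eq5d", "continuous", params={"mean": 0.55, "sd": 0.2}, loading=-0.5),
        VariableSpec("ceq_credibility", "continuous", params={"mean": 18.0, "sd": 4.0}, loading=0.1),
        VariableSpec("ceq_expectancy", "continuous", params=_CEQ, loading=-0.2),
    ] + [
        VariableSpec(name, "count", params={"lam": lam}, loading=0.3)
        for name, lam, _ in ticp_items
    ]
    miss_rates = {
        "ceq_credibility": 0.037,
        "ceq_expectancy": 0.041,
        "eq5d": 0.016,
        "antidepressants": 0.012,
        "prior_psychotherapy": 0.404,
        "melancholic_episode": 0.143,
        "dysthymia": 0.053,
        "comorbid_anxiety": 0.024,
    }
    miss_rates.update({name: rate for name, _, rate in ticp_items})
    beta_tau = {
        "phq9_baseline": 0.55,
        "ceq_expectancy": -0.25,
        "ticp_outpatient_psychotherapy_days": -0.35,
        "ticp_psychiatrist_visits": 0.45,
        # TAU works ~2 points better in Denmark; Denmark is the reference
        # level, so the contrast sits on the other three countries
        "country=France": 2.0,
        "country=Netherlands": 2.0,
        "country=Switzerland": 2.0,
        "ticp_day_psychiatric_hospital": 0.4,
    }
    beta_blend = {
        "phq9_baseline": 0.5,
        "ticp_regular_admissions": 1.2,
        "eq5d": -3.0,
        "ceq_expectancy": -0.3,
        "ticp_selfhelp_groups": 0.8,
        "marital_status=widowed": 2.5,
    }
    return ScenarioConfig(
        n_patients=251,
        covariate_schema=tuple(schema),
        beta_tau=beta_tau,
        beta_blend=beta_blend,
        intercept_tau=4.0,
        intercept_blend=8.0,
        noise_sd=4.0,
        miss_rates=miss_rates,
        outcome_dropout_rate=0.024,
        seed=seed,
    )


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Return a fully specified scenario configuration by name.

    ``null`` — prognostic baseline-severity effect only, identical in both
    arms (every true PAI is zero); ``prognostic_only`` — several shared
    prognostic effects, still no prescriptive contrast; ``prescriptive`` —
    n=500 with one binary marker carrying opposite-signed (+4/-4 point)
    arm-specific effects at noise_sd=4; ``ecompared_like`` — n=251, 28
    candidate predictors of mixed type with 2-41% per-item missingness and
    a small outcome-dropout rate.
    """
    builders = {
        "null": _null_config,
        "prognostic_only": _prognostic_only_config,
        "prescriptive": _prescriptive_config,
        "ecompared_like": _ecompared_like_config,
    }
    if name not in builders:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    return builders[name](seed)


def write_trial_with_truth(
    table: TrialTable, truth: SyntheticTruth, config: ScenarioConfig, path: str | Path
) -> None:
    """Write the trial CSV with ground truth and config in the sidecar."""
    from .trial import write_trial

    write_trial(
        table,
        path,
        extra={"truth": truth.to_records(), "config": config.to_dict()},
    )


def read_truth(path: str | Path) -> SyntheticTruth:
    """Recover the ground-truth record from a trial CSV sidecar."""
    sidecar = read_sidecar(path)
    if "truth" not in sidecar:
        raise KeyError(f"no ground truth stored alongside {path}")
    return SyntheticTruth(pd.DataFrame(sidecar["truth"]))
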