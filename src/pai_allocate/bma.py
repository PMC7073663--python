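"""Bayesian model averaging for Gaussian linear models, ZS-null prior.

For each treatment arm the 12-week outcome is regressed on subsets of
the encoded baseline predictors. A model is an inclusion vector gamma
over the p candidate columns (the intercept is always included). Under
Zellner's g-prior the Bayes factor of model gamma against the
intercept-only null has the closed conditional form

    log BF(gamma | g) = ((n - 1 - p_g) / 2) * log(1 + g)
                        - ((n - 1) / 2) * log(1 + g * (1 - R^2_g)),

where p_g is the number of included columns and R^2_g the coefficient of
determination of the OLS fit of the centered data. The Zellner-Siow
(JZS, "ZS-null") prior places a Cauchy prior on the coefficients via the
mixture g ~ Inverse-Gamma(1/2, n*alpha/2), with Jeffreys' prior on the
error scale; the marginal Bayes factor integrates the conditional form
over that mixing density. The integral is evaluated by a Laplace
approximation on the log-g scale; a slow adaptive-quadrature evaluator
is provided as the independent oracle.

Posterior model probabilities renormalize exp(log BF) * prior over the
evaluated model set; per-column posterior inclusion probabilities (PIPs)
are the posterior mass of models containing the column. Model spaces up
to ``enumeration_limit`` columns are enumerated exhaustively; larger
spaces are explored with an initial Metropolis-Hastings chain over
inclusion vectors followed by adaptive sampling of distinct models
without replacement (the MCMC+BAS scheme).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class BMAConfig:
    """Prior and budget settings.

    ``alpha`` is the squared scale of the ZS mixing density (default 1);
    ``model_prior`` is ``uniform`` over the 2^p space or
    ``beta_binomial`` (a=b=1, uniform on model size); ``n_models`` is the
    distinct-model budget of the sampler (default 30 000);
    ``enumeration_limit`` is the largest p enumerated exhaustively.
    """

    alpha: float = 1.0
    model_prior: str = "uniform"
    n_models: int = 30_000
    mcmc_iterations: int | None = None
    seed: int = 0
    enumeration_limit: int = 20

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.model_prior not in ("uniform", "beta_binomial"):
            raise ValueError("model_prior must be 'uniform' or 'beta_binomial'")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "model_prior": self.model_prior,
            "n_models": self.n_models,
            "mcmc_iterations": self.mcmc_iterations,
            "seed": self.seed,
            "enumeration_limit": self.enumeration_limit,
        }


@dataclass
class BMAResult:
    """Posterior over the evaluated model space for one arm.

    ``gammas`` is the (m, p) boolean inclusion matrix of all evaluated
    models; ``posterior`` renormalizes exp(log_marginal + log_prior) over
    that set; ``pip`` maps column names to posterior inclusion
    probabilities. ``top_models(K)`` mirrors the published five-best-model
    layout (Bayes factor vs. the best model, number of variables, R^2,
    log marginal likelihood, posterior probability).
    """

    arm: str | None
    columns: list[str]
    gammas: np.ndarray
    log_marginals: np.ndarray
    r_squared: np.ndarray
    log_prior: np.ndarray
    posterior: np.ndarray
    pip: pd.Series
    method: str
    n_models_evaluated: int
    notes: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.columns)

    def _order(self) -> np.ndarray:
        # descending posterior; ties -> fewer variables, then lexicographic gamma
        p_gamma = self.gammas.sum(axis=1)
        keys = [tuple(row) for row in self.gammas.astype(int)]
        return np.asarray(
            sorted(
                range(len(self.posterior)),
                key=lambda i: (-self.posterior[i], p_gamma[i], keys[i]),
            )
        )

    def top_models(self, K: int = 5) -> pd.DataFrame:
        return top_model_table(self, K)

    def best_gamma(self) -> np.ndarray:
        return self.gammas[self._order()[0]]

    def to_dict(self) -> dict:
        order = self._order()
        return {
            "arm": self.arm,
            "columns": self.columns,
            "method": self.method,
            "n_models_evaluated": int(self.n_models_evaluated),
            "pip": {c: float(self.pip[c]) for c in self.columns},
            "notes": list(self.notes),
            "models": [
                {
                    "gamma": "".join(map(str, self.gammas[i].astype(int))),
                    "log_marginal": float(self.log_marginals[i]),
                    "r_squared": float(self.r_squared[i]),
                    "posterior_prob": float(self.posterior[i]),
                }
                for i in order
            ],
        }


# ---------------------------------------------------------------------------
# marginal likelihoods


def log_bf_given_g(n: int, p_gamma: int, r_squared: float, g: float) -> float:
    """Log Bayes factor vs. the null model under a fixed g-prior scale.

    Intercept and error scale are handled by centering; the null model
    (p_gamma = 0) returns 0 for any g. Raises for a saturated fit
    (R^2 = 1, diverging marginal) or non-positive g.
    """
    if g <= 0:
        raise ValueError("g must be > 0")
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must lie in [0, 1)")
    if n <= p_gamma + 1:
        raise ValueError("need n > p_gamma + 1")
    if p_gamma == 0:
        return 0.0
    return 0.5 * (n - 1 - p_gamma) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(
        g * (1.0 - r_squared)
    )


def _log_integrand(t: np.ndarray | float, n: int, p_gamma: int, r_squared: float, alpha: float):
    """Log of [conditional BF x ZS mixing density x Jacobian] at t = log g.

    g ~ Inverse-Gamma(1/2, n*alpha/2); the +t term is the Jacobian of the
    change of variables g = e^t.
    """
    g = np.exp(t)
    lbf = 0.5 * (n - 1 - p_gamma) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(
        g * (1.0 - r_squared)
    )
    half_scale = n * alpha / 2.0
    lprior = 0.5 * np.log(half_scale) - gammaln(0.5) - 1.5 * t - half_scale / g
    return lbf + lprior + t


def _check_zs_args(n: int, p_gamma: int, r_squared: float, alpha: float) -> None:
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("r_squared must lie in [0, 1) (saturated fit diverges)")
    if n <= p_gamma + 1:
        raise ValueError("need n > p_gamma + 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")


def log_marginal_zs_quadrature(
    n: int, p_gamma: int, r_squared: float, alpha: float = 1.0
) -> float:
    """ZS-null log Bayes factor by adaptive quadrature (the slow oracle)."""
    if p_gamma == 0:
        return 0.0
    _check_zs_args(n, p_gamma, r_squared, alpha)
    grid = np.linspace(-30.0, 40.0, 2001)
    vals = _log_integrand(grid, n, p_gamma, r_squared, alpha)
    shift = float(np.max(vals))
    val, _ = integrate.quad(
        lambda t: np.exp(_log_integrand(t, n, p_gamma, r_squared, alpha) - shift),
        -60.0,
        80.0,
        points=[float(grid[np.argmax(vals)])],
        limit=400,
    )
    return float(np.log(val) + shift)


def log_marginal_zs(n: int, p_gamma: int, r_squared: float, alpha: float = 1.0) -> float:
    """ZS-null log Bayes factor vs. the null, by Laplace approximation.

    The integrand is maximized over t = log g (one-dimensional bounded
    search), the curvature taken from a central second difference, and
    the Gaussian volume added. The null model short-circuits to exactly
    0. A non-concave or non-finite curvature falls back to the
    quadrature evaluator with a warning.
    """
    if p_gamma == 0:
        return 0.0
    _check_zs_args(n, p_gamma, r_squared, alpha)
    A = 0.5 * (n - 1 - p_gamma)
    B = 0.5 * (n - 1)
    c = 1.0 - r_squared
    s = n * alpha / 2.0

    def fprime(t: float) -> float:
        g = np.exp(t)
        return A * g / (1.0 + g) - B * c * g / (1.0 + c * g) - 0.5 + s / g

    # f' decreases from +inf (t -> -inf) to -(p_gamma+1)/2 (t -> +inf):
    # the integrand on the log-g scale has a single interior mode.
    lo, hi = -15.0, 35.0
    try:
        while fprime(lo) <= 0 and lo > -60.0:
            lo -= 10.0
        while fprime(hi) >= 0 and hi < 80.0:
            hi += 10.0
        t0 = float(optimize.brentq(fprime, lo, hi, xtol=1e-10))
        g0 = np.exp(t0)
        x0 = c * g0
        curv = A * g0 / (1.0 + g0) ** 2 - B * x0 / (1.0 + x0) ** 2 - s / g0
    except ValueError:
        curv = np.nan
    if not np.isfinite(curv) or curv >= 0:
        warnings.warn("Laplace mode search failed; falling back to quadrature")
        return log_marginal_zs_quadrature(n, p_gamma, r_squared, alpha)
    # higher-order correction from the 3rd/4th derivatives at the mode
    # (the integrand on the log-g scale is visibly skewed for small p_gamma)
    h3 = (
        A * g0 * (1.0 - g0) / (1.0 + g0) ** 3
        - B * x0 * (1.0 - x0) / (1.0 + x0) ** 3
        + s / g0
    )
    h4 = (
        A * g0 * (1.0 - 4.0 * g0 + g0 * g0) / (1.0 + g0) ** 4
        - B * x0 * (1.0 - 4.0 * x0 + x0 * x0) / (1.0 + x0) ** 4
        - s / g0
    )
    cc = -curv
    correction = 1.0 + h4 / (8.0 * cc * cc) + 5.0 * h3 * h3 / (24.0 * cc**3)
    f0 = float(_log_integrand(t0, n, p_gamma, r_squared, alpha))
    base = f0 + 0.5 * np.log(2.0 * np.pi / cc)
    if correction <= 0 or not np.isfinite(correction):
        warnings.warn("Laplace correction degenerate; falling back to quadrature")
        return log_marginal_zs_quadrature(n, p_gamma, r_squared, alpha)
    return float(base + np.log(correction))


# ---------------------------------------------------------------------------
# model scoring machinery


class _ModelScorer:
    """Scores inclusion vectors against centered data via the Gram matrix."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: BMAConfig):
        self.n = X.shape[0]
        self.p = X.shape[1]
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.G = Xc.T @ Xc
        self.b = Xc.T @ yc
        self.yy = float(yc @ yc)
        self.config = config
        if self.yy <= 0:
            raise ValueError("outcome is constant; nothing to model")

    def r_squared(self, gamma: np.ndarray) -> float:
        idx = np.flatnonzero(gamma)
        if idx.size == 0:
            return 0.0
        S = self.G[np.ix_(idx, idx)]
        b = self.b[idx]
        try:
            coef = cho_solve(cho_factor(S, lower=True), b)
        except (LinAlgError, ValueError):
            coef, *_ = np.linalg.lstsq(S, b, rcond=None)
        r2 = float(b @ coef) / self.yy
        return min(max(r2, 0.0), 1.0 - 1e-12)

    def log_prior(self, p_gamma: int) -> float:
        if self.config.model_prior == "uniform":
            return -self.p * np.log(2.0)
        # beta-binomial(1,1): uniform over model size, then over models of that size
        return float(
            -np.log(self.p + 1.0)
            - (gammaln(self.p + 1) - gammaln(p_gamma + 1) - gammaln(self.p - p_gamma + 1))
        )

    def score(self, gamma: np.ndarray) -> tuple[float, float]:
        """(log marginal, R^2); unidentifiable models get -inf mass."""
        p_gamma = int(gamma.sum())
        if p_gamma >= self.n - 1:
            return -np.inf, 0.0
        r2 = self.r_squared(gamma)
        return log_marginal_zs(self.n, p_gamma, r2, self.config.alpha), r2


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), list(X.columns)
    X = np.asarray(X, dtype=np.float64)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _finalize(
    arm: str | None,
    columns: list[str],
    gammas: np.ndarray,
    log_marginals: np.ndarray,
    r2: np.ndarray,
    log_prior: np.ndarray,
    method: str,
    notes: list[str],
) -> BMAResult:
    log_post = log_marginals + log_prior
    log_z = logsumexp(log_post)
    posterior = np.exp(log_post - log_z)
    pip_vals = posterior @ gammas
    pip = pd.Series(pip_vals, index=columns, dtype=float)
    return BMAResult(
        arm=arm,
        columns=columns,
        gammas=gammas.astype(bool),
        log_marginals=log_marginals,
        r_squared=r2,
        log_prior=log_prior,
        posterior=posterior,
        pip=pip,
        method=method,
        n_models_evaluated=len(posterior),
        notes=notes,
    )


def enumerate_models(X, y, config: BMAConfig | None = None, arm: str | None = None) -> BMAResult:
    """Exhaustive BMA over all 2^p predictor subsets.

    ``X`` is a coded design matrix (DataFrame or array), ``y`` the
    outcome vector; both are centered internally before the marginal
    likelihood is computed. Requires p <= ``enumeration_limit``.
    """
    config = config or BMAConfig()
    Xm, columns = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    p = Xm.shape[1]
    if p == 0:
        raise ValueError("no candidate predictors")
    if p > config.enumeration_limit:
        raise ValueError(
            f"p = {p} exceeds enumeration_limit = {config.enumeration_limit}; use mcmc_bas"
        )
    notes: list[str] = []
    if Xm.shape[0] <= p + 1:
        warnings.warn("fewer rows than p + 2; large models are unidentifiable and skipped")
        notes.append("n <= p + 1: saturated models assigned zero mass")
    scorer = _ModelScorer(Xm, y, config)
    m = 1 << p
    gammas = ((np.arange(m)[:, None] >> np.arange(p)[None, :]) & 1).astype(np.uint8)
    log_marginals = np.empty(m)
    r2 = np.empty(m)
    log_prior = np.empty(m)
    for i in range(m):
        g = gammas[i]
        log_marginals[i], r2[i] = scorer.score(g)
        log_prior[i] = scorer.log_prior(int(g.sum()))
    return _finalize(arm, columns, gammas, log_marginals, r2, log_prior, "enumeration", notes)


def mcmc_bas(X, y, config: BMAConfig | None = None, arm: str | None = None) -> BMAResult:
    """BMA by MCMC exploration plus sampling without replacement.

    Phase 1 runs a Metropolis-Hastings chain over inclusion vectors
    (single-bit flips with occasional include/exclude swaps) targeting
    exp(log marginal + log prior), collecting every distinct visited
    model. Phase 2 draws further distinct models with independent
    per-column Bernoulli probabilities set to the running PIP estimates
    (clamped to [0.025, 0.975]), skipping already-scored models and
    refreshing the estimates periodically; when the remaining budget can
    cover the whole unscored space — or duplicate sampling starves with
    few models left — the remainder is enumerated, which makes the
    sampler exactly equivalent to enumeration once the budget exhausts
    the 2^p space. Final PIPs and posterior probabilities renormalize
    over all unique scored models.
    """
    config = config or BMAConfig()
    Xm, columns = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    p = Xm.shape[1]
    if p == 0:
        raise ValueError("no candidate predictors")
    if config.n_models < 10:
        raise ValueError("n_models budget must be at least 10")
    rng = np.random.default_rng(config.seed)
    scorer = _ModelScorer(Xm, y, config)
    notes: list[str] = []

    budget = int(min(config.n_models, 1 << min(p, 62)))
    scored: dict[bytes, tuple[float, float, float]] = {}

    def score_new(gamma: np.ndarray) -> tuple[float, float, float]:
        key = gamma.tobytes()
        hit = scored.get(key)
        if hit is None:
            lm, r2 = scorer.score(gamma)
            lp = scorer.log_prior(int(gamma.sum()))
            hit = (lm, r2, lp)
            scored[key] = hit
        return hit

    # --- phase 1: Metropolis-Hastings over inclusion vectors
    gamma = (rng.random(p) < 0.5).astype(np.uint8)
    lm, _, lp = score_new(gamma)
    log_target = lm + lp
    visit_incl = np.zeros(p)
    visits = 0
    phase1_unique = max(budget // 2, 1)
    max_steps = config.mcmc_iterations or 20 * budget
    steps = 0
    while len(scored) < phase1_unique and steps < max_steps:
        steps += 1
        prop = gamma.copy()
        if rng.random() < 0.1 and 0 < gamma.sum() < p:
            # swap one included with one excluded column
            inc = np.flatnonzero(gamma)
            exc = np.flatnonzero(1 - gamma)
            prop[rng.choice(inc)] = 0
            prop[rng.choice(exc)] = 1
        else:
            j = rng.integers(p)
            prop[j] = 1 - prop[j]
        lm_p, _, lp_p = score_new(prop)
        log_target_p = lm_p + lp_p
        if np.log(rng.random()) < log_target_p - log_target:
            gamma, log_target = prop, log_target_p
        visit_incl += gamma
        visits += 1

    # provisional PIPs from MCMC visit frequencies
    pip_est = visit_incl / visits if visits else np.full(p, 0.5)

    # --- phase 2: adaptive sampling without replacement
    eps = 0.025
    consecutive_dup = 0
    refresh_every = 500
    since_refresh = 0
    while len(scored) < budget:
        remaining = budget - len(scored)
        space_left = (1 << p) - len(scored) if p < 62 else None
        if space_left is not None and (space_left <= remaining or consecutive_dup > 2000):
            if space_left <= remaining and p <= 25:
                # enumerate the unscored remainder: exhaustion equivalence
                for i in range(1 << p):
                    g = ((i >> np.arange(p)) & 1).astype(np.uint8)
                    score_new(g)
                notes.append("model space exhausted by enumeration of the remainder")
                break
            if consecutive_dup > 2000:
                notes.append("duplicate-skip starvation; finished early")
                break
        probs = np.clip(pip_est, eps, 1.0 - eps)
        g = (rng.random(p) < probs).astype(np.uint8)
        key = g.tobytes()
        if key in scored:
            consecutive_dup += 1
            continue
        consecutive_dup = 0
        score_new(g)
        since_refresh += 1
        if since_refresh >= refresh_every:
            since_refresh = 0
            keys = list(scored.keys())
            lposts = np.array([scored[k][0] + scored[k][2] for k in keys])
            gam = np.frombuffer(b"".join(keys), dtype=np.uint8).reshape(len(keys), p)
            w = np.exp(lposts - logsumexp(lposts))
            pip_est = w @ gam

    keys = list(scored.keys())
    gammas = np.frombuffer(b"".join(keys), dtype=np.uint8).reshape(len(keys), p).copy()
    log_marginals = np.array([scored[k][0] for k in keys])
    r2 = np.array([scored[k][1] for k in keys])
    log_prior = np.array([scored[k][2] for k in keys])
    return _finalize(arm, columns, gammas, log_marginals, r2, log_prior, "mcmc_bas", notes)


def top_model_table(result: BMAResult, K: int = 5) -> pd.DataFrame:
    """Ranked top-K model report.

    Columns mirror the published layout: Bayes factor relative to the
    best model (best = 1, descending), number of included variables,
    R^2, log marginal likelihood and normalized posterior probability,
    plus the included column names.
    """
    if result.n_models_evaluated == 0:
        raise ValueError("empty result")
    order = result._order()
    if K > len(order):
        warnings.warn(f"only {len(order)} models evaluated; truncating K = {K}")
        K = len(order)
    idx = order[:K]
    best_lm = result.log_marginals[idx[0]]
    rows = []
    for rank, i in enumerate(idx, start=1):
        included = [c for c, g in zip(result.columns, result.gammas[i]) if g]
        rows.append(
            {
                "Model": rank,
                "Bayes Factor": float(np.exp(result.log_marginals[i] - best_lm)),
                "Number of Variables": int(result.gammas[i].sum()),
                "R2": float(result.r_squared[i]),
                "Log Marginal Likelihood": float(result.log_marginals[i]),
                "Posterior Probability": float(result.posterior[i]),
                "Variables": ", ".join(included) if included else "(null)",
            }
        )
    return pd.DataFrame(rows)
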