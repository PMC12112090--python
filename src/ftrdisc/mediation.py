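"""Bayesian moderated mediation for language → future-tense use → discounting.

The system is two normal linear equations,

    fut_i      = λ1 + α·lang_i + e1_i
    log(k)_i   = λ2 + τ'·lang_i + β1·fut_i + β2·fut_i·lang_i + e2_i

with lang a 0/1 indicator (Dutch = 0, English = 1) and fut the participant's
standardized future-tense proportion.  Under flat priors on coefficients and
log-scale, the posterior is available in closed form: the residual variance
follows a scaled inverse-chi-square marginal with n − p degrees of freedom,
and coefficients are conditionally multivariate normal around the
least-squares solution.  Draws are therefore sampled exactly (no MCMC),
seeded, and reproducible.

Indirect effects are path products per posterior draw.  Because the
mediator→outcome slope is moderated by language, the indirect effect is
conditional: ind = a·(β1 + β2·lang), where the a-term is α for English and
the mediator intercept λ1 for Dutch.  Crossing one language's a-term with
the other's slope gives the counterfactual panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HYPOTHESIS_SIGNS = ("negative", "positive")
SOURCES = ("english", "dutch")


def power_rule(m: int, groups: int = 1) -> int:
    """Rule-of-thumb minimum N: (50 + 8m) per group of independent slopes."""
    if m < 0 or groups < 1:
        raise ValueError("require m >= 0 and groups >= 1")
    return (50 + 8 * m) * groups


def zscale(values) -> np.ndarray:
    """Mean-center and scale to unit sample standard deviation (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column (zero variance)")
    return (x - x.mean()) / sd


def sample_posterior(X, y, n_draws: int = 4000, seed=0,
                     column_names: Sequence[str] | None = None):
    """Exact flat-prior posterior draws for a normal linear model.

    Returns ``(coef_draws, sigma_draws)`` with shapes (n_draws, p) and
    (n_draws,).  σ² is drawn from its scaled inverse-chi-square marginal
    (df = n − p); coefficients from the conditional MVN around the
    least-squares solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} rows, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = list(column_names) if column_names else [f"x{j}" for j in range(p)]
        for j in range(p):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"design matrix is rank deficient: column {names[j]!r} "
                                 "is linearly dependent on the others")
        raise ValueError("design matrix is rank deficient")
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    chol = np.linalg.cholesky(xtx_inv)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = rss / rng.chisquare(df, size=n_draws)
    z = rng.standard_normal((n_draws, p))
    coefs = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    return coefs, np.sqrt(sigma2)


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint draws for the mediator and outcome equations."""

    lambda1: np.ndarray
    alpha: np.ndarray
    sigma1: np.ndarray
    lambda2: np.ndarray
    tau_prime: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    sigma2: np.ndarray
    n_draws: int
    seed: int

    def path(self, name: str) -> np.ndarray:
        return getattr(self, name)


def fit_mediation(rows: pd.DataFrame, n_draws: int = 4000, seed: int = 0) -> PosteriorDraws:
    """Sample the two-equation system from participant rows.

    ``rows`` needs columns ``language_indicator`` (0 = Dutch, 1 = English),
    ``fut_z`` (standardized future-tense proportion) and ``log_k``.  The two
    equations share no parameters and are sampled independently.
    """
    lang = np.asarray(rows["language_indicator"], dtype=float)
    fut = np.asarray(rows["fut_z"], dtype=float)
    log_k = np.asarray(rows["log_k"], dtype=float)
    levels = set(np.unique(lang))
    if not levels <= {0.0, 1.0}:
        raise ValueError(f"language_indicator must be 0/1, got {sorted(levels)}")
    if levels != {0.0, 1.0}:
        raise ValueError("both languages must be present to fit the mediation system")
    n = lang.size
    ones = np.ones(n)
    ss = np.random.SeedSequence(seed)
    seeds = [np.random.default_rng(child) for child in ss.spawn(2)]
    xm = np.column_stack([ones, lang])
    cm, s1 = sample_posterior(xm, fut, n_draws, seeds[0],
                              column_names=["intercept", "language"])
    xy = np.column_stack([ones, lang, fut, fut * lang])
    cy, s2 = sample_posterior(xy, log_k, n_draws, seeds[1],
                              column_names=["intercept", "language", "fut", "fut:language"])
    return PosteriorDraws(
        lambda1=cm[:, 0], alpha=cm[:, 1], sigma1=s1,
        lambda2=cy[:, 0], tau_prime=cy[:, 1], beta1=cy[:, 2], beta2=cy[:, 3],
        sigma2=s2, n_draws=n_draws, seed=seed,
    )


def mediator_design(rows: pd.DataFrame) -> np.ndarray:
    lang = np.asarray(rows["language_indicator"], dtype=float)
    return np.column_stack([np.ones(lang.size), lang])


def outcome_design(rows: pd.DataFrame) -> np.ndarray:
    lang = np.asarray(rows["language_indicator"], dtype=float)
    fut = np.asarray(rows["fut_z"], dtype=float)
    return np.column_stack([np.ones(lang.size), lang, fut, fut * lang])


def conditional_indirect(draws: PosteriorDraws, alpha_source: str,
                         beta_source: str) -> np.ndarray:
    """Per-draw conditional indirect effect a·(β1 + β2·lang).

    ``alpha_source`` picks the a-term (α for English, λ1 for Dutch);
    ``beta_source`` picks the mediator→outcome slope (β1 + β2 for English,
    β1 for Dutch).  Mixed sources are the counterfactual combinations.
    """
    if alpha_source not in SOURCES or beta_source not in SOURCES:
        raise ValueError(f"sources must be one of {SOURCES}")
    a = draws.alpha if alpha_source == "english" else draws.lambda1
    b = draws.beta1 + draws.beta2 if beta_source == "english" else draws.beta1
    return a * b


def point_indirect(coefs: Mapping[str, float], alpha_source: str,
                   beta_source: str) -> float:
    """Indirect effect from point coefficients (product of posterior means)."""
    if alpha_source not in SOURCES or beta_source not in SOURCES:
        raise ValueError(f"sources must be one of {SOURCES}")
    a = coefs["alpha"] if alpha_source == "english" else coefs["lambda1"]
    b = coefs["beta1"] + (coefs["beta2"] if beta_source == "english" else 0.0)
    return a * b


@dataclass(frozen=True)
class MediationSummary:
    est: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    pp: float
    hypothesis_sign: str


def summarize(draw_vector, hypothesis_sign: str = "negative") -> MediationSummary:
    """Posterior mean, central 90/95% intervals, and sign probability pp."""
    if hypothesis_sign not in HYPOTHESIS_SIGNS:
        raise ValueError(f"hypothesis_sign must be one of {HYPOTHESIS_SIGNS}")
    d = np.asarray(draw_vector, dtype=float)
    if d.size == 0:
        raise ValueError("empty draw vector")
    lo90, hi90 = np.percentile(d, [5.0, 95.0])
    lo95, hi95 = np.percentile(d, [2.5, 97.5])
    pp = float(np.mean(d < 0) if hypothesis_sign == "negative" else np.mean(d > 0))
    return MediationSummary(
        est=float(d.mean()),
        ci90=(float(lo90), float(hi90)),
        ci95=(float(lo95), float(hi95)),
        pp=pp,
        hypothesis_sign=hypothesis_sign,
    )


def bayes_r2(coef_draws: np.ndarray, sigma_draws: np.ndarray, X) -> tuple[np.ndarray, dict]:
    """Per-draw Bayesian R²: var(Xβ) / (var(Xβ) + σ²), with mean and 95% interval."""
    X = np.asarray(X, dtype=float)
    fitted = coef_draws @ X.T
    var_fit = fitted.var(axis=1, ddof=1)
    r2 = var_fit / (var_fit + np.asarray(sigma_draws) ** 2)
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return r2, {"mean": float(r2.mean()), "ci95": (float(lo), float(hi))}
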