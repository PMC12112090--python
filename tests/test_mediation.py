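"""Flat-prior posterior sampling, path products, and summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ftrdisc import synth
from ftrdisc.mediation import (
    MediationSummary, PosteriorDraws, bayes_r2, conditional_indirect,
    fit_mediation, point_indirect, power_rule, sample_posterior, summarize,
    zscale, outcome_design, mediator_design,
)


def test_zscale():
    assert zscale([1, 2, 3]) == pytest.approx([-1, 0, 1])
    x = zscale(np.random.default_rng(0).normal(5, 3, 200))
    assert abs(x.mean()) < 1e-12
    assert x.std(ddof=1) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant|variance"):
        zscale([5, 5, 5])


@pytest.mark.parametrize("m, groups, n", [(8, 2, 228), (0, 1, 50), (1, 1, 58)])
def test_power_rule(m, groups, n):
    assert power_rule(m, groups) == n


def _fixture_design(seed=0, n=80):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
    beta = np.array([1.0, -0.5, 2.0])
    y = X @ beta + rng.normal(0, 1.5, n)
    return X, y, beta


def test_posterior_means_match_least_squares():
    # independent oracle: closed-form OLS fit
    X, y, _ = _fixture_design()
    coefs, sigma = sample_posterior(X, y, n_draws=8000, seed=42)
    ols = sm.OLS(y, X).fit()
    mc_se = coefs.std(axis=0, ddof=1) / np.sqrt(coefs.shape[0])
    assert np.all(np.abs(coefs.mean(axis=0) - ols.params) < 3 * mc_se)
    # sigma draws concentrate near the OLS residual scale
    assert sigma.mean() == pytest.approx(np.sqrt(ols.scale), rel=0.1)


def test_sampler_is_seeded():
    X, y, _ = _fixture_design()
    c1, s1 = sample_posterior(X, y, n_draws=500, seed=7)
    c2, s2 = sample_posterior(X, y, n_draws=500, seed=7)
    assert np.array_equal(c1, c2) and np.array_equal(s1, s2)
    c3, _ = sample_posterior(X, y, n_draws=500, seed=8)
    assert not np.array_equal(c1, c3)


def test_sampler_rejects_rank_deficiency():
    X, y, _ = _fixture_design()
    X_bad = np.column_stack([X, X[:, 1] * 2])
    with pytest.raises(ValueError, match="rank deficient"):
        sample_posterior(X_bad, y, n_draws=10, seed=0,
                         column_names=["const", "x1", "x2", "x1_copy"])
    with pytest.raises(ValueError, match="rows"):
        sample_posterior(X[:4], y[:4], n_draws=10, seed=0)


def test_ci_coverage_calibration():
    # 200 replicates at known truth: 95% central intervals cover ~95%
    rng = np.random.default_rng(123)
    beta = np.array([0.5, -1.0])
    cover = 0
    for _ in range(200):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = X @ beta + rng.normal(0, 1, 40)
        coefs, _ = sample_posterior(X, y, n_draws=1000, seed=rng.integers(2**31))
        lo, hi = np.percentile(coefs[:, 1], [2.5, 97.5])
        cover += lo <= beta[1] <= hi
    assert 0.90 <= cover / 200 <= 0.99


def _cohort_rows(params, seed):
    cohort = synth.gen_cohort(synth.with_seed(params, seed))
    return pd.DataFrame({
        "language_indicator": cohort.language_indicator,
        "fut_z": cohort.fut_z_latent,
        "log_k": cohort.log_k_latent,
    })


def test_fit_mediation_recovers_generating_coefficients():
    params = synth.default_params("study1")
    truth = {"lambda1": params.lambda1, "alpha": params.alpha,
             "tau_prime": params.tau_prime, "beta1": params.beta1,
             "beta2": params.beta2}
    hits = {k: 0 for k in truth}
    n_rep = 20
    for rep in range(n_rep):
        draws = fit_mediation(_cohort_rows(params, rep), n_draws=1500, seed=rep)
        for name, value in truth.items():
            vec = draws.path(name)
            if abs(vec.mean() - value) <= 2 * vec.std(ddof=1):
                hits[name] += 1
    for name, h in hits.items():
        assert h / n_rep >= 0.85, f"{name}: {h}/{n_rep} within 2 posterior SDs"


def test_fit_mediation_requires_both_languages():
    params = synth.default_params("study1")
    rows = _cohort_rows(params, 0)
    only_english = rows[rows.language_indicator == 1]
    with pytest.raises(ValueError, match="both languages"):
        fit_mediation(only_english, n_draws=10, seed=0)


def test_duplicated_data_shrinks_posterior_sd():
    params = synth.default_params("study1")
    rows = _cohort_rows(params, 3)
    d1 = fit_mediation(rows, n_draws=4000, seed=5)
    d2 = fit_mediation(pd.concat([rows, rows], ignore_index=True), n_draws=4000, seed=5)
    assert d2.alpha.mean() == pytest.approx(d1.alpha.mean(), abs=3 * d1.alpha.std())
    assert d2.alpha.std() < d1.alpha.std()
    assert d2.beta2.std() < d1.beta2.std()


def _point_draws(**kw):
    n = 100
    vals = dict(lambda1=0.0, alpha=0.0, sigma1=1.0, lambda2=0.0, tau_prime=0.0,
                beta1=0.0, beta2=0.0, sigma2=1.0)
    vals.update(kw)
    return PosteriorDraws(**{k: np.full(n, v) for k, v in vals.items()},
                          n_draws=n, seed=0)


def test_conditional_indirect_point_masses():
    # study-level posterior means as point masses reproduce the table products
    d1 = _point_draws(alpha=1.36, beta1=0.26, beta2=-0.90)
    assert conditional_indirect(d1, "english", "english")[0] == pytest.approx(-0.8704)
    d2 = _point_draws(lambda1=-0.75, beta1=-0.07)
    assert conditional_indirect(d2, "dutch", "dutch")[0] == pytest.approx(0.0525)
    # interaction off: the beta source no longer matters
    d3 = _point_draws(alpha=1.0, lambda1=-0.5, beta1=0.4, beta2=0.0)
    assert np.array_equal(conditional_indirect(d3, "english", "english"),
                          conditional_indirect(d3, "english", "dutch"))
    with pytest.raises(ValueError):
        conditional_indirect(d3, "english", "german")


def test_point_indirect_matches_draws_for_point_masses():
    coefs = dict(lambda1=-0.65, alpha=1.36, beta1=0.26, beta2=-0.90)
    d = _point_draws(**{k: v for k, v in coefs.items()})
    for a in ("english", "dutch"):
        for b in ("english", "dutch"):
            assert point_indirect(coefs, a, b) == pytest.approx(
                conditional_indirect(d, a, b)[0])


def test_summarize():
    s = summarize(np.array([-2.0, -1.0, 0.0, 1.0]), "negative")
    assert s.est == pytest.approx(-0.5)
    assert s.pp == pytest.approx(0.5)
    all_neg = summarize(-np.abs(np.random.default_rng(0).normal(size=500)) - 0.01,
                        "negative")
    assert all_neg.pp == 1.0
    sym = summarize(np.random.default_rng(1).normal(0, 1, 20000), "negative")
    assert sym.pp == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ValueError):
        summarize([], "negative")
    with pytest.raises(ValueError):
        summarize([1.0], "downward")


def test_summary_nesting_and_pp_flip():
    d = np.random.default_rng(2).normal(-0.5, 1, 5000)
    s_neg = summarize(d, "negative")
    s_pos = summarize(d, "positive")
    assert s_neg.ci95[0] <= s_neg.ci90[0] <= s_neg.ci90[1] <= s_neg.ci95[1]
    assert s_neg.pp + s_pos.pp == pytest.approx(1.0)  # no draw is exactly zero


def test_path_algebra_identity():
    # posterior linear predictor for English rows = lambda1 + alpha, draw by draw
    params = synth.default_params("study1")
    rows = _cohort_rows(params, 11)
    draws = fit_mediation(rows, n_draws=200, seed=11)
    X = mediator_design(rows)
    eng = X[:, 1] == 1
    coefs = np.column_stack([draws.lambda1, draws.alpha])
    pred_eng = coefs @ X[eng][0]
    assert np.allclose(pred_eng, draws.lambda1 + draws.alpha)


def test_bayes_r2_limits_and_simulation():
    rng = np.random.default_rng(9)
    X = np.column_stack([np.ones(600), rng.normal(size=600)])
    # intercept-only coefficients: no explained variance
    coefs = np.tile([2.0, 0.0], (300, 1))
    r2, _ = bayes_r2(coefs, np.ones(300), X)
    assert np.all(r2 == 0)
    # sigma -> 0: R2 -> 1
    coefs = np.tile([0.0, 1.0], (300, 1))
    r2, _ = bayes_r2(coefs, np.full(300, 1e-9), X)
    assert np.all(r2 > 0.999)
    # population R2 = 0.5: slope 1, unit predictor variance, unit noise
    y = X @ [0.0, 1.0] + rng.normal(0, 1, 600)
    cd, sd = sample_posterior(X, y, n_draws=2000, seed=10)
    _, summary = bayes_r2(cd, sd, X)
    assert summary["mean"] == pytest.approx(0.5, abs=0.07)


def test_outcome_design_shape():
    rows = pd.DataFrame({"language_indicator": [0, 1], "fut_z": [0.3, -0.3],
                         "log_k": [-3.0, -2.0]})
    X = outcome_design(rows)
    assert X.shape == (2, 4)
    assert X[1, 3] == pytest.approx(-0.3)  # interaction column = fut * lang
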