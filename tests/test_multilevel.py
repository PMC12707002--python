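"""Random-intercept logistic likelihood, ICC/PCV arithmetic, model ladder."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

from gcci import SyntheticConfig, generate_survey
from gcci.multilevel import (
    fit_random_intercept_logit,
    icc_latent,
    lr_test,
    marginal_loglik,
    model_ladder,
    pcv,
)


def _simulate(J, nj, beta, sigma2, seed, x_col=True):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(J) * np.sqrt(sigma2)
    cl = np.repeat(np.arange(J), nj)
    X = np.ones((J * nj, 1))
    if x_col:
        X = np.column_stack([X, rng.standard_normal(J * nj)])
    y = (rng.random(J * nj) < expit(X @ np.asarray(beta) + u[cl])).astype(float)
    return y, X, cl


def test_icc_latent_values():
    assert icc_latent(0.0) == 0.0
    assert icc_latent(np.pi**2 / 3) == pytest.approx(0.5, abs=1e-15)
    assert 100 * icc_latent(0.423) == pytest.approx(11.4, abs=0.05)
    assert 100 * icc_latent(0.240) == pytest.approx(6.8, abs=0.05)
    with pytest.raises(ValueError):
        icc_latent(-0.1)
    # strictly increasing
    grid = np.linspace(0, 2, 20)
    assert np.all(np.diff([icc_latent(v) for v in grid]) > 0)


def test_pcv_values():
    assert pcv(0.472, 0.472) == 0.0
    assert pcv(0.472, 0.240) == pytest.approx(49.15, abs=0.01)
    assert pcv(0.4, 0.1) == pytest.approx(75.0)
    with pytest.raises(ValueError):
        pcv(0.0, 0.1)


def test_sigma_zero_matches_ordinary_logistic():
    y, X, cl = _simulate(20, 30, [-0.5, 0.8], 0.3, seed=1)
    beta = np.array([-0.4, 0.7])
    ours = marginal_loglik(y, X, cl, beta, 0.0)
    plain = sm.Logit(y, X).loglike(beta)
    assert ours == pytest.approx(plain, abs=1e-6)


def test_quadrature_convergence():
    y, X, cl = _simulate(30, 40, [-0.5, 0.8], 0.5, seed=2)
    beta = np.array([-0.5, 0.8])
    l7 = marginal_loglik(y, X, cl, beta, 0.5, quad_points=7)
    l15 = marginal_loglik(y, X, cl, beta, 0.5, quad_points=15)
    assert abs(l7 - l15) < 1e-3


def test_single_fit_recovery():
    y, X, cl = _simulate(100, 100, [-1.0, 0.5], 0.4, seed=3)
    fit = fit_random_intercept_logit(y, X, cl)
    assert fit.beta[0] == pytest.approx(-1.0, abs=3 * fit.se[0])
    assert fit.beta[1] == pytest.approx(0.5, abs=3 * fit.se[1])
    assert fit.sigma2_u == pytest.approx(0.4, abs=0.15)
    ors = fit.odds_ratios
    np.testing.assert_allclose(ors, np.exp(fit.beta))
    lo, hi = fit.or_conf_int().T
    assert np.all(lo < ors) and np.all(ors < hi)


def test_singleton_clusters_carry_no_clustering_information():
    """With one observation per cluster sigma2_u is unidentified (rescaling
    beta along the logistic-normal ridge); the fit cannot beat ordinary
    logistic regression and implies the same marginal probabilities."""
    rng = np.random.default_rng(4)
    n = 400
    x = rng.standard_normal(n)
    y = (rng.random(n) < expit(-0.3 + 0.6 * x)).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit = fit_random_intercept_logit(y, X, np.arange(n), compute_se=False)
    glm = sm.Logit(y, X).fit(disp=0)
    assert fit.loglik == pytest.approx(glm.llf, abs=0.5)
    # marginal success probabilities agree despite the ridge
    from numpy.polynomial.hermite import hermgauss

    t, w = hermgauss(40)
    s = np.sqrt(fit.sigma2_u)
    p_mixed = (
        w[None, :] / np.sqrt(np.pi) * expit((X @ fit.beta)[:, None] + np.sqrt(2) * s * t[None, :])
    ).sum(axis=1)
    np.testing.assert_allclose(p_mixed, glm.predict(), atol=0.02)


def test_matches_lme4_glmer():
    """Independent oracle: lme4's adaptive-quadrature fit on the same data."""
    y, X, cl = _simulate(30, 20, [-0.8, 0.7], 0.5, seed=5)
    fit = fit_random_intercept_logit(y, X, cl, quad_points=25, compute_se=False)
    pd.DataFrame({"y": y.astype(int), "x": X[:, 1], "cl": cl}).to_csv(
        "/tmp/gcci_glmer.csv", index=False
    )
    rcode = (
        'suppressMessages(library(lme4));'
        'd <- read.csv("/tmp/gcci_glmer.csv");'
        'm <- glmer(y ~ x + (1|cl), data=d, family=binomial, nAGQ=25);'
        'cat(fixef(m), as.numeric(VarCorr(m)$cl), as.numeric(logLik(m)), sep="\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
    )
    b0, b1, s2, ll = map(float, out.stdout.split())
    assert fit.beta[0] == pytest.approx(b0, abs=1e-3)
    assert fit.beta[1] == pytest.approx(b1, abs=1e-3)
    assert fit.sigma2_u == pytest.approx(s2, abs=1e-3)
    assert fit.loglik == pytest.approx(ll, abs=1e-2)


def test_separation_raises_named_error():
    rng = np.random.default_rng(6)
    n = 200
    x = rng.standard_normal(n)
    y = (x > 0).astype(float)  # perfectly separated
    X = pd.DataFrame({"intercept": np.ones(n), "sep_col": x})
    with pytest.raises(Exception, match="[Ss]eparat"):
        fit_random_intercept_logit(y, X, np.repeat(np.arange(10), 20), compute_se=False)


def test_singular_design_is_an_error():
    y, X, cl = _simulate(10, 20, [-0.5, 0.5], 0.2, seed=7)
    X2 = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match="singular"):
        fit_random_intercept_logit(y, X2, cl)


def test_lr_test_basics():
    y, X, cl = _simulate(20, 20, [-0.5, 0.5], 0.2, seed=8)
    fit = fit_random_intercept_logit(y, X, cl, compute_se=False,
                                     names=["intercept", "x"])
    stat, df, p = lr_test(fit, fit)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-6)
    # chi-square arithmetic
    assert chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)
    f0 = fit_random_intercept_logit(y, X[:, :1], cl, compute_se=False,
                                    names=["intercept"])
    stat, df, p = lr_test(f0, fit)
    assert df == 1 and stat >= 0
    with pytest.raises(ValueError, match="nested"):
        lr_test(
            fit_random_intercept_logit(y, X[:, 1:], cl, compute_se=False, names=["z"]),
            fit,
        )


def test_pcv_recovery_with_known_explainable_share():
    """Half the level-2 outcome variance is context-driven by construction;
    the ladder's PCV should land near 50% on average."""
    vals = []
    for rep in range(10):
        cfg = SyntheticConfig(
            seed=1000 + rep, n_per_community=200, outcome_covariate_effects={}
        )
        df = generate_survey(cfg)
        from gcci import community_prevalence, fit_one_factor, score_communities, select_k

        cp = community_prevalence(df)
        s = score_communities(fit_one_factor(cp), cp)
        g = select_k(s.score, s.community_id)
        y = df["multiparity"].to_numpy(float)
        cl = df["community_id"].to_numpy()
        X0 = pd.DataFrame({"intercept": np.ones(len(df))})
        X1 = X0.copy()
        lab = df["community_id"].map(dict(zip(g.community_id, g.label_per_community)))
        for name in g.labels[:-1]:
            X1[f"gccs[{name}]"] = (lab == name).astype(float)
        f0 = fit_random_intercept_logit(y, X0, cl, quad_points=7, compute_se=False)
        f1 = fit_random_intercept_logit(y, X1, cl, quad_points=7, compute_se=False)
        vals.append(pcv(f0.sigma2_u, f1.sigma2_u))
    assert abs(np.mean(vals) - 50.0) < 10.0


def test_ladder_with_no_context_effect_has_near_zero_pcv():
    cfg = SyntheticConfig(
        n_communities=40,
        n_per_community=150,
        outcome_context_effect=0.0,
        outcome_residual_community_sd=0.5,
        seed=13,
    )
    df = generate_survey(cfg)
    from gcci import community_prevalence, fit_one_factor, score_communities, select_k

    cp = community_prevalence(df)
    s = score_communities(fit_one_factor(cp), cp)
    g = select_k(s.score, s.community_id)
    ladder = model_ladder(df, g, quad_points=7)
    assert abs(ladder.decomposition["model3_gccs"].pcv) < 25.0
    # adding GCCS leaves individual-level signs unchanged
    b2 = ladder.fits["model2_individual"].to_frame()["beta"]
    b3 = ladder.fits["model3_gccs"].to_frame()["beta"]
    shared = [n for n in b2.index if n != "intercept"]
    assert np.all(np.sign(b2[shared]) == np.sign(b3[shared]))
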