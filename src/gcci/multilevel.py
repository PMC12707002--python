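"""Random-intercept logistic regression with adaptive Gauss-Hermite quadrature.

Two-level model for a binary outcome y_ij of individual i in community j:

    logit P(y_ij = 1) = x_ij' beta + u_j,   u_j ~ N(0, sigma2_u)

The marginal likelihood integrates the community intercept out with
adaptive Gauss-Hermite quadrature: per cluster, the integrand's mode and
curvature are located by Newton's method (the integrand is log-concave) and
the quadrature grid is recentred and rescaled there, so a modest number of
nodes (default 12) is accurate even for large clusters.  At sigma2_u = 0
the rule is exact and the marginal likelihood equals the ordinary logistic
likelihood.

Variance decomposition follows the latent-variable convention: the level-1
residual variance of a logistic model is fixed at pi^2/3, giving

    ICC = sigma2_u / (sigma2_u + pi^2/3)

and the proportional change in level-2 variance (PCV) between nested models
is (sigma2_ref - sigma2_model) / sigma2_ref * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2
import statsmodels.api as sm

from .clustering import GCCSAssignment

__all__ = [
    "MLFit",
    "VarianceDecomposition",
    "ModelLadder",
    "fit_random_intercept_logit",
    "icc_latent",
    "pcv",
    "lr_test",
    "model_ladder",
]

_LOG_SIGMA2_BOUNDS = (-20.0, 10.0)
_HALF_LOG_2PI = 0.5 * np.log(2 * np.pi)


@dataclass
class MLFit:
    """Fitted random-intercept logistic model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray | None
    sigma2_u: float
    sigma2_se: float | None
    loglik: float
    n: int
    n_clusters: int
    quad_points: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def or_conf_int(self, level: float = 0.95) -> np.ndarray:
        if self.se is None:
            raise ValueError("fit was run without standard errors")
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        return np.column_stack([lo, hi])

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # + sigma2_u

    def to_frame(self) -> pd.DataFrame:
        ci = self.or_conf_int() if self.se is not None else np.full((len(self.beta), 2), np.nan)
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se if self.se is not None else np.nan,
                "odds_ratio": self.odds_ratios,
                "or_low": ci[:, 0],
                "or_high": ci[:, 1],
            },
            index=self.names,
        )


@dataclass
class VarianceDecomposition:
    icc: float
    pcv: float | None  # percent change vs the reference model; None for the first


class _AGQLoglik:
    """Marginal log-likelihood evaluator, vectorized across clusters."""

    def __init__(self, y: np.ndarray, X: np.ndarray, cluster: np.ndarray, n_quad: int):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        _, inv = np.unique(cluster, return_inverse=True)
        self.cl = inv
        self.J = inv.max() + 1
        t, w = hermgauss(n_quad)
        self.t = t
        self.logw = np.log(w)
        self.n_quad = n_quad

    def _cluster_loglik(self, eta: np.ndarray) -> np.ndarray:
        ll = self.y * eta - np.logaddexp(0.0, eta)
        return np.bincount(self.cl, weights=ll, minlength=self.J)

    def __call__(self, beta: np.ndarray, sigma: float) -> float:
        xb = self.X @ beta
        u = np.zeros(self.J)
        # Newton for the per-cluster posterior mode; log-concave => safe.
        for _ in range(50):
            eta = xb + sigma * u[self.cl]
            p = expit(eta)
            grad = sigma * np.bincount(self.cl, weights=self.y - p, minlength=self.J) - u
            hess = -(sigma**2) * np.bincount(
                self.cl, weights=p * (1 - p), minlength=self.J
            ) - 1.0
            u = u - grad / hess
            if np.max(np.abs(grad)) < 1e-10:
                break
        eta = xb + sigma * u[self.cl]
        p = expit(eta)
        hess = -(sigma**2) * np.bincount(
            self.cl, weights=p * (1 - p), minlength=self.J
        ) - 1.0
        tau = 1.0 / np.sqrt(-hess)

        # Adaptive rule: L_j = sqrt(2) tau_j sum_q w_q e^{t_q^2} g_j(u_j + sqrt2 tau_j t_q)
        # with g_j(u) = exp(cluster loglik at u) * phi(u).
        nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * self.t[None, :]  # (J, Q)
        terms = np.empty((self.J, self.n_quad))
        for q in range(self.n_quad):
            uq = nodes[:, q]
            llj = self._cluster_loglik(xb + sigma * uq[self.cl])
            terms[:, q] = self.logw[q] + self.t[q] ** 2 + llj - 0.5 * uq**2 - _HALF_LOG_2PI
        logL = 0.5 * np.log(2.0) + np.log(tau) + logsumexp(terms, axis=1)
        return float(logL.sum())


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def fit_random_intercept_logit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    cluster: np.ndarray | pd.Series,
    quad_points: int = 12,
    names: list[str] | None = None,
    compute_se: bool = True,
    tol: float = 1e-8,
    start: np.ndarray | None = None,
) -> MLFit:
    """Maximize the AGQ marginal likelihood; Wald inference.

    ``X`` must include the intercept column if one is wanted.  The level-2
    variance is optimized on the log scale; its standard error is recovered
    by the delta method.  Separation (coefficients diverging) is reported
    with the offending covariate named.
    """
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        Xv = X.to_numpy(float)
    else:
        Xv = np.atleast_2d(np.asarray(X, float))
        names = names or [f"x{k}" for k in range(Xv.shape[1])]
    yv = np.asarray(y, float)
    clv = np.asarray(cluster)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(clv).size < 2:
        raise ValueError("need at least 2 clusters")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is singular (collinear columns)")

    ll = _AGQLoglik(yv, Xv, clv, quad_points)

    if start is None:
        glm = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
        theta0 = np.concatenate([glm.params, [np.log(0.2)]])
    else:
        theta0 = np.asarray(start, float)

    def negll(theta: np.ndarray) -> float:
        return -ll(theta[:-1], np.exp(theta[-1] / 2.0))

    p = Xv.shape[1]
    bounds = [(None, None)] * p + [_LOG_SIGMA2_BOUNDS]
    res = minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
    )
    theta = res.x
    beta = theta[:-1]
    big = np.abs(beta) > 30
    if big.any():
        bad = [names[k] for k in np.flatnonzero(big)]
        raise ValueError(f"apparent separation: diverging coefficient(s) for {bad}")
    sigma2 = float(np.exp(theta[-1]))
    loglik = -float(res.fun)

    se = sigma2_se = None
    if compute_se:
        H = _num_hessian(negll, theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = d[:-1]
        sigma2_se = float(sigma2 * d[-1])  # delta method on log sigma2

    return MLFit(
        names=list(names),
        beta=beta,
        se=se,
        sigma2_u=sigma2,
        sigma2_se=sigma2_se,
        loglik=loglik,
        n=int(yv.size),
        n_clusters=int(np.unique(clv).size),
        quad_points=quad_points,
    )


def marginal_loglik(
    y, X, cluster, beta: np.ndarray, sigma2_u: float, quad_points: int = 12
) -> float:
    """Evaluate the AGQ marginal log-likelihood at given parameter values."""
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ll = _AGQLoglik(np.asarray(y, float), Xv, np.asarray(cluster), quad_points)
    return ll(np.asarray(beta, float), float(np.sqrt(sigma2_u)))


def icc_latent(sigma2_u: float) -> float:
    """Latent-scale ICC: sigma2_u / (sigma2_u + pi^2 / 3)."""
    if sigma2_u < 0:
        raise ValueError("sigma2_u must be nonnegative")
    return sigma2_u / (sigma2_u + np.pi**2 / 3.0)


def pcv(sigma2_ref: float, sigma2_model: float) -> float:
    """Proportional change in level-2 variance, percent of the reference."""
    if sigma2_ref <= 0:
        raise ValueError("reference variance must be positive")
    return (sigma2_ref - sigma2_model) / sigma2_ref * 100.0


def lr_test(fit_restricted: MLFit, fit_full: MLFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested random-intercept fits."""
    if fit_restricted.n != fit_full.n:
        raise ValueError("fits use different numbers of observations")
    if not set(fit_restricted.names) <= set(fit_full.names):
        raise ValueError("models are not nested (parameter names differ)")
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    df = fit_full.n_params - fit_restricted.n_params
    if df < 0:
        raise ValueError("restricted model has more parameters than the full model")
    # df == 0 (identical models): the statistic is 0 up to optimizer noise
    p = float(chi2.sf(stat, df)) if (df > 0 and stat > 0) else 1.0
    return float(stat), int(df), p


@dataclass
class ModelLadder:
    """Three-model ladder: null, individual attributes, + GCCS."""

    fits: dict[str, MLFit]
    decomposition: dict[str, VarianceDecomposition]
    lr_stat: float
    lr_df: int
    lr_pvalue: float

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for name, fit in self.fits.items():
            d = self.decomposition[name]
            rows[name] = {
                "level2_variance": fit.sigma2_u,
                "level2_variance_se": fit.sigma2_se,
                "icc_percent": 100 * d.icc,
                "pcv_percent": d.pcv,
                "minus2_loglik": -2 * fit.loglik,
                "n": fit.n,
            }
        return pd.DataFrame(rows).T


_EDU_SECONDARY = ("secondary", "upper_intermediate")
_EDU_UNIVERSITY = ("university", "postgraduate")


def ladder_design(data: pd.DataFrame, gccs: GCCSAssignment | None = None) -> pd.DataFrame:
    """Covariate design for the model ladder.

    Age grand-mean-centered; education dummies (ref: less than secondary);
    wealth quintile dummies (ref: poorest); early marriage; child death;
    optionally GCCS category dummies (ref: most restrictive).
    """
    needed = ["age", "education_level", "wealth_quintile", "child_marriage", "child_death"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    D = pd.DataFrame(index=data.index)
    D["intercept"] = 1.0
    D["age_centered"] = data["age"] - data["age"].mean()
    D["education_secondary"] = data["education_level"].isin(_EDU_SECONDARY).astype(float)
    D["education_university"] = data["education_level"].isin(_EDU_UNIVERSITY).astype(float)
    for q in (2, 3, 4, 5):
        D[f"wealth_{q}"] = (data["wealth_quintile"] == q).astype(float)
    D["early_married"] = data["child_marriage"].astype(float)
    D["child_death"] = data["child_death"].astype(float)
    if gccs is not None:
        label_map = dict(zip(gccs.community_id, gccs.label_per_community))
        lab = data["community_id"].map(label_map)
        for name in gccs.labels[:-1]:  # ref: most restrictive (highest mean)
            D[f"gccs[{name}]"] = (lab == name).astype(float)
    return D


def model_ladder(
    data: pd.DataFrame,
    gccs: GCCSAssignment,
    outcome: str = "multiparity",
    quad_points: int = 12,
) -> ModelLadder:
    """Fit the null / individual / individual+GCCS ladder and decompose variance.

    Reports the latent-scale ICC per model, the PCV of each model against
    the preceding one, and the likelihood-ratio test of adding the GCCS
    block to the individual-attributes model.
    """
    y = data[outcome].to_numpy(float)
    cl = data["community_id"].to_numpy()

    X1 = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    X2 = ladder_design(data)
    X3 = ladder_design(data, gccs)

    fit1 = fit_random_intercept_logit(y, X1, cl, quad_points)
    fit2 = fit_random_intercept_logit(y, X2, cl, quad_points)
    start3 = np.concatenate(
        [fit2.beta, np.zeros(X3.shape[1] - X2.shape[1]), [np.log(max(fit2.sigma2_u, 1e-4))]]
    )
    fit3 = fit_random_intercept_logit(y, X3, cl, quad_points, start=start3)

    decomp = {
        "model1_null": VarianceDecomposition(icc_latent(fit1.sigma2_u), None),
        "model2_individual": VarianceDecomposition(
            icc_latent(fit2.sigma2_u), pcv(fit1.sigma2_u, fit2.sigma2_u)
        ),
        "model3_gccs": VarianceDecomposition(
            icc_latent(fit3.sigma2_u), pcv(fit2.sigma2_u, fit3.sigma2_u)
        ),
    }
    stat, df, p = lr_test(fit2, fit3)
    return ModelLadder(
        fits={
            "model1_null": fit1,
            "model2_individual": fit2,
            "model3_gccs": fit3,
        },
        decomposition=decomp,
        lr_stat=stat,
        lr_df=df,
        lr_pvalue=p,
    )
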