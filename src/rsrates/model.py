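"""Random-intercept logistic regression by marginal maximum likelihood.

The risk model behind risk-standardized hospital rates: for patient j at
hospital i,

    logit Pr(y_ij = 1) = mu + alpha_i + x_ij' beta,   alpha_i ~ N(0, tau^2),

with the hospital effect integrated out of the likelihood.  The integral is
approximated per cluster by a Laplace approximation (default) or adaptive
Gauss-Hermite quadrature centred and scaled at the per-cluster posterior
mode; hospital effects are reported as posterior modes (empirical Bayes),
which shrink low-volume hospitals toward the national average.

Covariates are standardized internally for optimizer conditioning and the
coefficients returned on the original scale; the marginal log-likelihood is
invariant to that reparametrization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_TAU_FLOOR = 1e-6          # below this the model is treated as pooled logistic


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient; names the columns."""


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    Z = np.column_stack([np.ones(len(X)), X])
    _, R = np.linalg.qr(Z)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps * 100
    bad = np.where(diag < tol)[0]
    if bad.size:
        cols = [(["(intercept)"] + names)[j] for j in bad]
        raise CollinearityError(
            f"design matrix is rank-deficient; offending columns: {cols}"
        )


def _cluster_index(groups: np.ndarray):
    """Sort order, cluster labels, and reduceat start offsets."""
    order = np.argsort(groups, kind="mergesort")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    labels = g[starts]
    return order, labels, starts


def _posterior_modes(eta0, y, starts, tau2, a0=None, tol=1e-11, max_iter=100):
    """Vectorized per-cluster Newton for the mode of the posterior of alpha."""
    n_clusters = len(starts)
    a = np.zeros(n_clusters) if a0 is None else a0.copy()
    for _ in range(max_iter):
        eta = eta0 + np.repeat(a, np.diff(np.r_[starts, len(y)]))
        p = expit(eta)
        score = np.add.reduceat(y - p, starts) - a / tau2
        info = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / tau2
        step = score / info
        np.clip(step, -5.0, 5.0, out=step)
        a += step
        if np.max(np.abs(step)) < tol:
            break
    return a


def _bernoulli_ll(eta, y):
    # y*eta - log(1 + exp(eta)), numerically stable
    return y * eta - np.logaddexp(0.0, eta)


def marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    mu: float,
    beta: np.ndarray,
    tau: float,
    method: str = "laplace",
    n_quad: int = 9,
    _sorted=None,
) -> float:
    """Marginal log-likelihood with the random intercept integrated out.

    ``method='laplace'`` uses a per-cluster Laplace approximation;
    ``method='agq'`` uses ``n_quad``-node adaptive Gauss-Hermite quadrature
    centred at the posterior mode.  ``tau`` below 1e-6 degenerates to the
    pooled logistic log-likelihood.
    """
    if _sorted is None:
        order, labels, starts = _cluster_index(np.asarray(groups))
        Xs, ys = np.asarray(X, float)[order], np.asarray(y, float)[order]
    else:
        Xs, ys, starts = _sorted
    eta0 = mu + Xs @ np.asarray(beta, float)
    if tau < _TAU_FLOOR:
        return float(_bernoulli_ll(eta0, ys).sum())
    tau2 = tau * tau
    a = _posterior_modes(eta0, ys, starts, tau2)
    sizes = np.diff(np.r_[starts, len(ys)])
    eta = eta0 + np.repeat(a, sizes)
    p = expit(eta)
    spp = np.add.reduceat(p * (1.0 - p), starts)
    neg_hess = spp + 1.0 / tau2
    if method == "laplace":
        g_mode = (
            np.add.reduceat(_bernoulli_ll(eta, ys), starts)
            - a * a / (2.0 * tau2)
            - 0.5 * np.log(tau2)
            - 0.5 * _LOG_2PI
        )
        ll = g_mode + 0.5 * _LOG_2PI - 0.5 * np.log(neg_hess)
        return float(ll.sum())
    if method != "agq":
        raise ValueError("method must be 'laplace' or 'agq'")
    nodes, wts = hermgauss(n_quad)
    sigma = 1.0 / np.sqrt(neg_hess)
    terms = np.empty((n_quad, len(starts)))
    for k, (z, w) in enumerate(zip(nodes, wts)):
        ak = a + np.sqrt(2.0) * sigma * z
        etak = eta0 + np.repeat(ak, sizes)
        gk = (
            np.add.reduceat(_bernoulli_ll(etak, ys), starts)
            - ak * ak / (2.0 * tau2)
            - 0.5 * np.log(tau2)
            - 0.5 * _LOG_2PI
        )
        terms[k] = np.log(w) + z * z + gk
    ll = logsumexp(terms, axis=0) + 0.5 * np.log(2.0) + np.log(sigma)
    return float(ll.sum())


class RandomInterceptLogit(BaseEstimator):
    """Hierarchical logistic regression with a per-cluster random intercept.

    Parameters
    ----------
    method : {'laplace', 'agq'}
        Integral approximation for the marginal likelihood.  Laplace is the
        fast default; 'agq' (adaptive Gauss-Hermite, ``n_quad`` nodes) is the
        verification setting.
    n_quad : int
        Quadrature nodes for ``method='agq'`` (>= 9 recommended).
    tol : float
        Relative log-likelihood convergence tolerance.
    param_tol : float
        Parameter-change convergence tolerance.
    max_iter : int
        Optimizer iteration cap.
    standardize : bool
        Standardize covariates internally (coefficients are always reported
        on the original scale).
    warm_start : bool
        Reuse the previous fit's parameters as the starting point.

    Attributes
    ----------
    intercept_ : float         national intercept ``mu`` (logit scale)
    coef_ : ndarray            covariate log-odds ``beta`` (original scale)
    tau2_ : float              random-intercept variance
    alpha_ : pandas.Series     posterior-mode hospital effects, by cluster label
    loglik_ : float            marginal log-likelihood at the optimum
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        method: str = "laplace",
        n_quad: int = 9,
        tol: float = 1e-8,
        param_tol: float = 1e-6,
        max_iter: int = 200,
        standardize: bool = True,
        warm_start: bool = False,
    ):
        self.method = method
        self.n_quad = n_quad
        self.tol = tol
        self.param_tol = param_tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.warm_start = warm_start

    def fit(self, X, y, groups):
        feature_names = (
            list(X.columns) if isinstance(X, pd.DataFrame)
            else [f"x{j}" for j in range(np.asarray(X).shape[1])]
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(X) != len(y) or len(y) != len(groups):
            raise ValueError("X, y and groups must have matching first dimension")
        if len(y) == 0:
            raise ValueError("empty cohort")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        _check_collinear(X, feature_names)

        if self.standardize:
            mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Xw = (X - mean) / sd
        else:
            mean = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
            Xw = X

        order, labels, starts = _cluster_index(groups)
        Xs, ys = Xw[order], y[order]
        sorted_pack = (Xs, ys, starts)
        p = X.shape[1]

        if self.warm_start and hasattr(self, "_theta"):
            theta0 = self._theta.copy()
        else:
            # pooled-logistic start via a few Newton-Raphson (IRLS) steps
            b = np.zeros(p + 1)
            Z = np.column_stack([np.ones(len(ys)), Xs])
            for _ in range(25):
                pr = expit(Z @ b)
                W = pr * (1 - pr) + 1e-9
                grad = Z.T @ (ys - pr)
                H = (Z * W[:, None]).T @ Z
                step = np.linalg.solve(H, grad)
                b += step
                if np.max(np.abs(step)) < 1e-10:
                    break
            theta0 = np.r_[b, 0.2]

        def nll(theta):
            return -marginal_loglik(
                None, None, None,
                theta[0], theta[1:p + 1], theta[p + 1],
                method=self.method, n_quad=self.n_quad, _sorted=sorted_pack,
            )

        bounds = [(None, None)] * (p + 1) + [(0.0, 10.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={
                    "maxiter": self.max_iter,
                    "ftol": self.tol,
                    "gtol": self.param_tol,
                    "eps": 1e-6,
                },
            )
        theta = res.x
        self._theta = theta
        mu_std, beta_std, tau = theta[0], theta[1:p + 1], theta[p + 1]
        self.converged_ = bool(res.success and np.all(np.abs(beta_std) < 30))
        if not self.converged_:
            logger.warning(
                "random-intercept logit did not converge: %s", res.message
            )
        self.n_iter_ = int(res.nit)
        self.loglik_ = float(-res.fun)

        # back-transform to the original covariate scale
        beta = beta_std / sd
        mu = mu_std - float(beta_std @ (mean / sd))
        self.intercept_ = float(mu)
        self.coef_ = beta
        self.tau2_ = float(tau * tau) if tau >= _TAU_FLOOR else 0.0
        self.feature_names_in_ = feature_names

        if tau >= _TAU_FLOOR:
            eta0 = mu_std + Xs @ beta_std
            a = _posterior_modes(eta0, ys, starts, tau * tau)
            eta = eta0 + np.repeat(a, np.diff(np.r_[starts, len(ys)]))
            p = expit(eta)
            neg_hess = np.add.reduceat(p * (1 - p), starts) + 1.0 / (tau * tau)
            sd = 1.0 / np.sqrt(neg_hess)
        else:
            a = np.zeros(len(labels))
            sd = np.zeros(len(labels))
        idx = pd.Index(labels, name="hospital_id")
        self.alpha_ = pd.Series(a, index=idx, name="alpha_hat")
        # normal-approximation posterior SD of each hospital effect at the
        # mode (Laplace curvature); used for posterior draws in the bootstrap
        self.alpha_sd_ = pd.Series(sd, index=idx, name="alpha_sd")
        return self

    def predict_proba(self, X, groups=None):
        """Cluster-specific event probabilities; unknown clusters get the
        national intercept (alpha = 0).  Returns shape (n, 2) sklearn-style."""
        X = np.asarray(X, dtype=float)
        eta = self.intercept_ + X @ self.coef_
        if groups is not None:
            add = pd.Index(np.asarray(groups)).map(self.alpha_).to_numpy(float)
            eta = eta + np.nan_to_num(add, nan=0.0)
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, groups=None):
        return (self.predict_proba(X, groups)[:, 1] >= 0.5).astype(int)


@dataclass
class RiskModelFit:
    """Flat record of a fitted risk model, serializable to JSON."""

    mu: float
    beta: dict[str, float]
    tau2: float
    alpha_hat: dict[str, float]
    loglik: float
    converged: bool
    n_iterations: int

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "mu": self.mu, "beta": self.beta, "tau2": self.tau2,
                    "alpha_hat": self.alpha_hat, "loglik": self.loglik,
                    "converged": self.converged,
                    "n_iterations": self.n_iterations,
                },
                fh, indent=2,
            )


def fit_hierarchical_logit(
    cohort_table: pd.DataFrame,
    covariate_columns: list[str],
    method: str = "laplace",
    n_quad: int = 9,
    estimator: RandomInterceptLogit | None = None,
) -> tuple[RiskModelFit, RandomInterceptLogit]:
    """Fit the risk model on a cohort table (thin wrapper over the estimator)."""
    est = estimator or RandomInterceptLogit(method=method, n_quad=n_quad)
    est.fit(
        cohort_table[covariate_columns],
        cohort_table["outcome"],
        cohort_table["hospital_id"],
    )
    fit = RiskModelFit(
        mu=est.intercept_,
        beta=dict(zip(est.feature_names_in_, map(float, est.coef_))),
        tau2=est.tau2_,
        alpha_hat={str(k): float(v) for k, v in est.alpha_.items()},
        loglik=est.loglik_,
        converged=est.converged_,
        n_iterations=est.n_iter_,
    )
    return fit, est
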