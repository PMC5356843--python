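"""Newton/IRLS solver for binomial regression with a ridge fallback.

The stepwise-AIC search, the classifiability fits and the evaluation harness
perform on the order of 1e5 small logistic fits per run, so the solver is a
compact dense Newton iteration. When a fit diverges (perfect or quasi
separation: non-convergence or runaway coefficients) it is refit with a tiny
ridge penalty (1e-8) on the slopes only, under a hard iteration cap, and the
result is flagged. AIC always uses the unpenalized binomial log-likelihood
at the returned coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: |coefficient| beyond which a fit is treated as separated
COEF_BOUND = 30.0
#: ridge applied to slopes (never the intercept) in the fallback refit
RIDGE_FALLBACK = 1e-8


@dataclass
class LogisticFit:
    """A fitted binomial GLM (intercept in ``coef[0]``)."""

    coef: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    n_iter: int

    @property
    def aic(self) -> float:
        return 2.0 * self.coef.size - 2.0 * self.loglik

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.coef)


def binomial_loglik(X: np.ndarray, y: np.ndarray, coef: np.ndarray) -> float:
    eta = X @ coef
    # log L = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton(X, y, ridge, max_iter, tol=1e-8, beta0=None, stop_bound=None):
    n, p = X.shape
    pen = np.zeros(p)
    pen[1:] = ridge
    pen_diag = np.diag(pen)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def pll(b):
        return binomial_loglik(X, y, b) - 0.5 * float(pen @ (b * b))

    ll = pll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + pen_diag
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the penalized log-likelihood monotone
        t = 1.0
        new = beta + step
        ll_new = pll(new)
        while ll_new < ll - 1e-12 and t > 1e-6:
            t *= 0.5
            new = beta + t * step
            ll_new = pll(new)
        delta = float(np.max(np.abs(new - beta)))
        beta, ll = new, ll_new
        if delta < tol * (1.0 + float(np.max(np.abs(beta)))):
            converged = True
            break
        if stop_bound is not None and float(np.max(np.abs(beta))) > stop_bound:
            break  # runaway coefficients: separation, stop burning iterations
    return beta, converged, it


def _closed_form(X, y) -> LogisticFit | None:
    """Exact MLE for the two saturated cases: intercept-only, and intercept
    plus a single two-valued covariate (a 2x2 table). Returns None when the
    MLE is not finite (empty cell) or the design is not of this shape."""
    n, p = X.shape
    if p == 1:
        k = float(y.sum())
        if k <= 0 or k >= n:
            return None
        phat = k / n
        coef = np.array([np.log(phat / (1 - phat))])
        ll = k * np.log(phat) + (n - k) * np.log(1 - phat)
        return LogisticFit(coef, float(ll), True, False, 0)
    if p == 2:
        vals = np.unique(X[:, 1])
        if vals.size != 2:
            return None
        ll = 0.0
        etas = []
        for v in vals:
            m = X[:, 1] == v
            ng, kg = int(m.sum()), float(y[m].sum())
            if kg <= 0 or kg >= ng:
                return None
            pg = kg / ng
            etas.append(np.log(pg / (1 - pg)))
            ll += kg * np.log(pg) + (ng - kg) * np.log(1 - pg)
        slope = (etas[1] - etas[0]) / (vals[1] - vals[0])
        coef = np.array([etas[0] - slope * vals[0], slope])
        return LogisticFit(coef, float(ll), True, False, 0)
    return None


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    ridge: float = RIDGE_FALLBACK,
    coef_bound: float = COEF_BOUND,
    beta0: np.ndarray | None = None,
) -> LogisticFit:
    """Fit logit(P(y=1)) = X @ beta; X must carry an intercept column first.

    Divergence (non-convergence within ``max_iter`` or any |beta| above
    ``coef_bound``) triggers a flagged ridge refit so estimates stay finite.
    ``beta0`` warm-starts the Newton iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    direct = _closed_form(X, y)
    if direct is not None:
        if float(np.max(np.abs(direct.coef))) <= coef_bound:
            return direct
    beta, converged, it = _newton(X, y, 0.0, max_iter, beta0=beta0, stop_bound=coef_bound)
    separated = (
        not converged
        or not np.all(np.isfinite(beta))
        or float(np.max(np.abs(beta))) > coef_bound
    )
    if separated:
        beta, converged, it = _newton(X, y, ridge, max_iter=30)
        beta = np.clip(beta, -1e6, 1e6)
    return LogisticFit(
        coef=beta,
        loglik=binomial_loglik(X, y, beta),
        converged=converged,
        separation=separated,
        n_iter=it,
    )
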