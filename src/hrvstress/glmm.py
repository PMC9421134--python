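"""Maximum-likelihood Poisson regression with a Gaussian random intercept.

The marginal likelihood of a person's event counts integrates the
Poisson kernel over the person-level intercept:

    L_g(beta, sigma) = int  prod_j Pois(y_gj | exp(x_gj' beta + u)) N(u | 0, sigma^2) du

Because the random effect is a scalar shared by all of a person's
observations, the integrand collapses to

    exp( B_g + S_g u - A_g e^u - u^2 / (2 sigma^2) ),

with per-person sufficient statistics A_g = sum_j exp(x_gj' beta),
S_g = sum_j y_gj and B_g = sum_j (y_gj x_gj' beta - log y_gj!).  The
1-D integral is evaluated by adaptive Gauss-Hermite quadrature: each
person's nodes are centered at the integrand's mode (found by a
vectorized Newton iteration, for which f'(u) = S - A e^u - u/sigma^2
has a closed form) and scaled by the local curvature.  The marginal
log-likelihood is maximized over (beta, log sigma) by BFGS; standard
errors come from the numerical Hessian at the optimum.

This is the same estimator as lme4's ``glmer(..., family=poisson,
nAGQ=k)``; agreement is checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["PoissonRandomInterceptFit", "fit_poisson_glmm"]

_SQRT2 = np.sqrt(2.0)
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class PoissonRandomInterceptFit:
    """Fitted Poisson random-intercept model."""

    params: np.ndarray  # fixed-effect coefficients (log-rate scale)
    bse: np.ndarray
    sigma: float  # random-intercept SD
    sigma_se: float
    loglike: float
    exog_names: list[str]
    n_obs: int
    n_groups: int
    converged: bool
    message: str = ""
    nagq: int = 15
    cov_params: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def irr(self) -> np.ndarray:
        return np.exp(self.params)

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(np.abs(self.params / self.bse))
        return pd.DataFrame(
            {
                "term": self.exog_names,
                "estimate": self.params,
                "se": self.bse,
                "p": p,
                "ci_low": self.params - z * self.bse,
                "ci_high": self.params + z * self.bse,
                "irr": np.exp(self.params),
                "irr_low": np.exp(self.params - z * self.bse),
                "irr_high": np.exp(self.params + z * self.bse),
            }
        )


def _group_stats(y, X, beta, starts):
    eta = X @ beta
    A = np.add.reduceat(np.exp(eta), starts)
    B = np.add.reduceat(y * eta, starts)
    return A, B


def _newton_modes(S, A, sig2, n_iter=50, tol=1e-10):
    """Per-group mode of f(u) = S*u - A*exp(u) - u^2/(2 sig2)."""
    u = np.zeros_like(S, dtype=float)
    for _ in range(n_iter):
        e = A * np.exp(u)
        g = S - e - u / sig2
        h = -e - 1.0 / sig2
        step = g / h
        # dampen to keep exp(u) finite on wild starts
        step = np.clip(step, -5.0, 5.0)
        u = u - step
        if np.max(np.abs(g)) < tol:
            break
    return u


def _loglike(theta, y, X, starts, S, logfact, nodes, logw):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    sig2 = sigma * sigma
    A, B = _group_stats(y, X, beta, starts)
    u_hat = _newton_modes(S, A, sig2)
    curv = A * np.exp(u_hat) + 1.0 / sig2
    s = 1.0 / np.sqrt(curv)
    # u at nodes: (G, Q)
    u = u_hat[:, None] + _SQRT2 * s[:, None] * nodes[None, :]
    h = (
        B[:, None]
        + S[:, None] * u
        - A[:, None] * np.exp(u)
        - u * u / (2.0 * sig2)
        - log_sigma
        - 0.5 * _LOG_2PI
    )
    lse = special.logsumexp(logw[None, :] + nodes[None, :] ** 2 + h, axis=1)
    ll = lse + np.log(_SQRT2 * s)
    return float(np.sum(ll) - logfact)


def fit_poisson_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    exog_names: list[str] | None = None,
    nagq: int = 15,
    start_params: np.ndarray | None = None,
    sigma_fixed: float | None = None,
) -> PoissonRandomInterceptFit:
    """Fit y ~ Poisson(exp(X beta + u_group)), u ~ N(0, sigma^2).

    Parameters
    ----------
    y
        Non-negative integer counts.
    X
        Design matrix including the intercept column.
    groups
        Group (person) labels, any hashable dtype.
    nagq
        Number of adaptive Gauss-Hermite nodes (odd values recommended).
    sigma_fixed
        When given, the random-intercept SD is held at this value and
        only the fixed effects are estimated; ``sigma_fixed=0`` (held
        at a negligible value internally) reproduces an ordinary
        Poisson regression.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("outcome must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("all-zero outcome: Poisson rate unidentified")
    codes, _ = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    S = np.add.reduceat(y, starts)
    logfact = float(np.sum(special.gammaln(y + 1.0)))
    nodes, weights = np.polynomial.hermite.hermgauss(nagq)
    logw = np.log(weights)

    p = X.shape[1]
    if exog_names is None:
        exog_names = [f"x{i}" for i in range(p)]
    if start_params is None:
        # moment-style start: plain Poisson regression via a few IRLS steps
        beta0 = _poisson_irls(y, X)
        start_params = np.r_[beta0, np.log(0.5)]

    if sigma_fixed is not None:
        log_sig = np.log(max(sigma_fixed, 1e-8))

        def nll(beta):
            return -_loglike(np.r_[beta, log_sig], y, X, starts, S, logfact, nodes, logw)

        res = optimize.minimize(nll, start_params[:-1], method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
        hess = _numerical_hessian(nll, res.x)
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return PoissonRandomInterceptFit(
            params=res.x.copy(), bse=se, sigma=float(sigma_fixed), sigma_se=float("nan"),
            loglike=-float(res.fun), exog_names=list(exog_names), n_obs=int(y.size),
            n_groups=int(S.size), converged=bool(res.success), message=str(res.message),
            nagq=nagq, cov_params=cov,
        )

    def nll(theta):
        return -_loglike(theta, y, X, starts, S, logfact, nodes, logw)

    res = optimize.minimize(nll, start_params, method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:  # polish with Nelder-Mead if BFGS stalls near the optimum
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2

    theta = res.x
    hess = _numerical_hessian(nll, theta)
    try:
        cov = np.linalg.inv(hess)
        bad = np.any(np.diag(cov) <= 0)
    except np.linalg.LinAlgError:
        cov, bad = None, True
    if cov is None or bad:
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    sigma = float(np.exp(theta[-1]))
    return PoissonRandomInterceptFit(
        params=theta[:-1].copy(),
        bse=se[:-1],
        sigma=sigma,
        sigma_se=float(se[-1] * sigma),  # delta method from log-sigma
        loglike=-float(res.fun),
        exog_names=list(exog_names),
        n_obs=int(y.size),
        n_groups=int(S.size),
        converged=bool(res.success or np.isfinite(res.fun)),
        message=str(res.message),
        nagq=nagq,
        cov_params=cov,
    )


def _poisson_irls(y, X, n_iter=25):
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _numerical_hessian(f, x, eps=1e-5):
    n = x.size
    H = np.zeros((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H
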