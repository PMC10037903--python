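"""Beta mixed model for paired methylation-type data.

The 5-mC and 5-hmC proportions of one subject at one CpG are two
observations of a shared biological state, so the type-interaction model
regresses both jointly:

    logit mu_ij = x_ij' beta + b_i,   y_ij ~ Beta(mu_ij, phi_{type(j)}),
    b_i ~ N(0, sigma_b^2),

with a subject random intercept and a separate precision per methylation
type.  The marginal likelihood integrates the scalar random effect by
adaptive Gauss-Hermite quadrature: per subject the integrand is re-centered
at its posterior mode and re-scaled by the local curvature, so a modest
node count (default 15) is accurate even when the per-observation
likelihood is much sharper than the random-effect prior.

Precision parameters are optimized on the log scale, which enforces
positivity by construction and leaves the ML point estimates of phi
unchanged relative to an identity-scale parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, polygamma
from scipy.stats import norm

__all__ = ["TypeInteractionFit", "fit_beta_mixed"]

_ETA_CLIP = 30.0


@dataclass
class TypeInteractionFit:
    coef: np.ndarray
    se: np.ndarray
    names: list[str]
    phi: np.ndarray          # (2,) per-type precision, order (ref, alt)
    sigma2_b: float
    loglik: float
    converged: bool
    sigma_boundary: bool

    @property
    def pvalues(self):
        return 2.0 * norm.sf(np.abs(self.coef / self.se))

    def term(self, name):
        j = self.names.index(name)
        return self.coef[j], self.se[j], self.pvalues[j]


def _beta_logpdf(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))


class _Marginal:
    """Negative marginal log-likelihood with adaptive quadrature."""

    def __init__(self, X, y2, n_nodes=15, newton_steps=6):
        # X: (2n, p) stacked [type0 block; type1 block]; y2: (n, 2)
        self.X = X
        self.y2 = y2
        self.n = y2.shape[0]
        self.p = X.shape[1]
        x, w = hermgauss(n_nodes)
        self.qx = x
        self.logw = np.log(w)
        self.newton_steps = newton_steps
        self.ystar = np.log(y2) - np.log1p(-y2)

    def __call__(self, theta):
        n, p = self.n, self.p
        beta = theta[:p]
        phi = np.exp(theta[p:p + 2])           # (phi_ref, phi_alt)
        sigma = np.exp(theta[p + 2])
        eta0 = (self.X @ beta).reshape(2, n).T.copy()   # (n, 2)
        eta0 = np.clip(eta0, -_ETA_CLIP, _ETA_CLIP)
        y = self.y2
        phi_row = phi[None, :]

        # posterior mode of b_i by damped Newton with expected curvature;
        # fixed iteration count from zero keeps the function deterministic
        # in theta, which finite-difference gradients rely on
        b = np.zeros(n)
        for _ in range(self.newton_steps):
            mu = expit(np.clip(eta0 + b[:, None], -_ETA_CLIP, _ETA_CLIP))
            g = mu * (1.0 - mu)
            a1 = mu * phi_row
            a2 = (1.0 - mu) * phi_row
            score = np.sum(phi_row * (self.ystar - (digamma(a1) - digamma(a2))) * g,
                           axis=1) - b / sigma**2
            curv = np.sum(phi_row**2 * g**2 *
                          (polygamma(1, a1) + polygamma(1, a2)), axis=1) + 1.0 / sigma**2
            step = np.clip(score / curv, -2.0, 2.0)
            b = b + step
        mu = expit(np.clip(eta0 + b[:, None], -_ETA_CLIP, _ETA_CLIP))
        g = mu * (1.0 - mu)
        a1 = mu * phi_row
        a2 = (1.0 - mu) * phi_row
        curv = np.sum(phi_row**2 * g**2 *
                      (polygamma(1, a1) + polygamma(1, a2)), axis=1) + 1.0 / sigma**2
        scale = 1.0 / np.sqrt(curv)            # (n,)

        # adaptive nodes: b_ik = b_i + sqrt(2) * scale_i * x_k
        bk = b[:, None] + np.sqrt(2.0) * scale[:, None] * self.qx[None, :]  # (n, K)
        eta = eta0[:, :, None] + bk[:, None, :]                              # (n, 2, K)
        mu_k = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        mu_k = np.clip(mu_k, 1e-12, 1 - 1e-12)
        logf = np.sum(_beta_logpdf(y[:, :, None], mu_k, phi[None, :, None]),
                      axis=1)                                                # (n, K)
        log_prior = -0.5 * (bk / sigma)**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        h = logf + log_prior + self.qx[None, :]**2 + self.logw[None, :]
        hmax = h.max(axis=1, keepdims=True)
        ll_i = (np.log(np.sqrt(2.0) * scale)
                + hmax[:, 0] + np.log(np.sum(np.exp(h - hmax), axis=1)))
        val = -np.sum(ll_i)
        if not np.isfinite(val):
            return 1e12
        return val


def fit_beta_mixed(X, y2, names=None, n_nodes: int = 15,
                   start=None, max_restarts: int = 2) -> TypeInteractionFit:
    """Fit the beta mixed model for one CpG site.

    Parameters
    ----------
    X : (2n, p) array
        Stacked fixed-effect design: first n rows are the reference-type
        (5-mC) observations, last n rows the 5-hmC observations, in the
        same subject order.  Should include intercept, exposure,
        covariates, the Type indicator, and the Type x exposure column.
    y2 : (n, 2) array
        Per-subject (5-mC, 5-hmC) proportions, strictly inside (0, 1).
    """
    X = np.asarray(X, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y2.shape[0]
    p = X.shape[1]
    if X.shape[0] != 2 * n:
        raise ValueError("X must stack exactly two rows per subject")
    if np.any((y2 <= 0) | (y2 >= 1)):
        raise ValueError("responses must lie strictly inside (0, 1)")

    nll = _Marginal(X, y2, n_nodes=n_nodes)

    if start is None:
        # independent-rows beta fit with common precision for starting values
        from .betareg import fit_betareg_batch

        yflat = np.concatenate([y2[:, 0], y2[:, 1]])[:, None]
        init = fit_betareg_batch(X, yflat)
        start = np.concatenate([
            init.coef[:, 0],
            [np.log(init.phi[0]), np.log(init.phi[0])],
            [np.log(0.2)],
        ])

    bounds = ([(None, None)] * p
              + [(np.log(1.01), np.log(1e7))] * 2
              + [(np.log(1e-4), np.log(5.0))])
    best = None
    for attempt in range(max_restarts + 1):
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        start = res.x + np.random.default_rng(attempt).normal(scale=0.05,
                                                              size=len(start))
    theta = best.x
    se = _wald_se(nll, theta, p)
    sigma2 = float(np.exp(2 * theta[p + 2]))
    return TypeInteractionFit(
        coef=theta[:p],
        se=se,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        phi=np.exp(theta[p:p + 2]),
        sigma2_b=sigma2,
        loglik=-float(best.fun),
        converged=bool(best.success),
        sigma_boundary=sigma2 < 2.5e-4,
    )


def _wald_se(nll, theta, p):
    """Fixed-effect SEs from a central-difference observed information."""
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    grad_at = {}

    def grad(x):
        key = tuple(np.round(x, 12))
        if key not in grad_at:
            g = np.empty(k)
            for j in range(k):
                e = np.zeros(k)
                e[j] = h[j]
                g[j] = (nll(x + e) - nll(x - e)) / (2 * h[j])
            grad_at[key] = g
        return grad_at[key]

    H = np.empty((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        H[:, j] = (grad(theta + e) - grad(theta - e)) / (2 * h[j])
    H = 0.5 * (H + H.T)
    cov = np.linalg.pinv(H)
    var = np.clip(np.diag(cov)[:p], 0, None)
    return np.sqrt(var)
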