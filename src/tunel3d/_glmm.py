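"""Random-intercept mixed models via Gauss–Hermite quadrature.

Maximum-likelihood estimation for two likelihood families used by the
analysis layer: binomial logistic and cumulative-logit (proportional
odds) ordinal, each with a single Gaussian random intercept per cluster
(replicate). The marginal likelihood integrates the random effect with
Gauss–Hermite quadrature; with the default 25 nodes this is effectively
exact for the cluster sizes involved here. Standard errors come from
the numerically differentiated observed information at the optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess


class ConvergenceError(RuntimeError):
    """The likelihood could not be maximised (separation, flat outcome...)."""


def _quad(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return x, np.log(w) - 0.5 * np.log(np.pi)


def _group_index(groups) -> tuple[np.ndarray, int]:
    uniq, idx = np.unique(np.asarray(groups), return_inverse=True)
    return idx, len(uniq)


def _marginal_loglik(row_ll_fn, gidx, n_groups, n_quad):
    """Build the marginal log-likelihood given a per-row loglik function.

    ``row_ll_fn(eta_offset)`` must return an (nrows, K) array of row
    log-likelihoods at the K quadrature offsets.
    """
    x, logw = _quad(n_quad)

    def loglik(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        offsets = np.sqrt(2.0) * sigma * x  # (K,)
        rows = row_ll_fn(offsets)  # (nrows, K)
        per_cluster = np.zeros((n_groups, rows.shape[1]))
        np.add.at(per_cluster, gidx, rows)
        return float(logsumexp(per_cluster + logw, axis=1).sum())

    return loglik


def _fit(objective, start, n_beta):
    res = minimize(objective, start, method="L-BFGS-B")
    if not np.isfinite(res.fun):
        raise ConvergenceError("likelihood did not converge to a finite value")
    hess = approx_hess(res.x, objective)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full_like(res.x, np.nan)
    return res, se


def fit_binomial_glmm(
    successes,
    trials,
    X,
    groups,
    n_quad: int = 25,
) -> dict:
    """Binomial logistic regression with a cluster random intercept.

    ``successes`` / ``trials`` are per-row binomial counts (group size =
    trials is the size weighting), ``X`` the fixed-effect design with an
    intercept column first. Returns estimates, standard errors, the
    random-intercept SD and the maximised log-likelihood.
    """
    y = np.asarray(successes, float)
    n = np.asarray(trials, float)
    X = np.asarray(X, float)
    if np.any(y > n):
        raise ValueError("successes exceed trials")
    total_y, total_n = y.sum(), n.sum()
    if total_y == 0 or total_y == total_n:
        raise ConvergenceError("outcome has zero variance (all failures or all successes)")
    gidx, n_groups = _group_index(groups)

    def row_ll(offsets, beta):
        eta = (X @ beta)[:, None] + offsets[None, :]
        return y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)

    p = X.shape[1]
    rate = np.clip(total_y / total_n, 1e-6, 1 - 1e-6)
    start = np.r_[np.log(rate / (1 - rate)), np.zeros(p - 1), np.log(0.3)]

    def objective(theta):
        beta, log_sigma = theta[:p], theta[p]
        ll = _marginal_loglik(lambda off: row_ll(off, beta), gidx, n_groups, n_quad)
        return -ll(log_sigma)

    res, se = _fit(objective, start, p)
    return {
        "beta": res.x[:p],
        "se": se[:p],
        "sigma": float(np.exp(res.x[p])),
        "loglik": -float(res.fun),
        "n_obs": len(y),
        "n_groups": n_groups,
    }


def fit_cumulative_glmm(
    y_codes,
    X,
    groups,
    n_categories: int,
    n_quad: int = 25,
) -> dict:
    """Cumulative-logit (proportional odds) model with a random intercept.

    ``y_codes`` are ordinal codes 0..K-1; ``X`` carries the fixed
    effects *without* an intercept (the K-1 thresholds absorb it).
    ``P(Y <= k) = logistic(kappa_k - x'beta - u)``.
    """
    y = np.asarray(y_codes, int)
    X = np.asarray(X, float)
    K = n_categories
    observed = np.unique(y)
    if len(observed) < 2:
        raise ConvergenceError("ordinal outcome has a single observed category")
    gidx, n_groups = _group_index(groups)
    p = X.shape[1]

    freqs = np.bincount(y, minlength=K) / len(y)
    cum = np.clip(np.cumsum(freqs)[:-1], 1e-4, 1 - 1e-4)
    kappa0 = np.log(cum / (1 - cum))
    start = np.r_[kappa0[0], np.log(np.maximum(np.diff(kappa0), 1e-2)), np.zeros(p), np.log(0.3)]

    def unpack(theta):
        kappa = np.r_[theta[0], theta[0] + np.cumsum(np.exp(theta[1 : K - 1]))]
        beta = theta[K - 1 : K - 1 + p]
        return kappa, beta, theta[-1]

    def row_ll(offsets, kappa, beta):
        eta = (X @ beta)[:, None] + offsets[None, :]  # (n, Kq)
        upper = np.where(y[:, None] < K - 1, kappa[np.minimum(y, K - 2)][:, None] - eta, np.inf)
        lower = np.where(y[:, None] > 0, kappa[np.maximum(y - 1, 0)][:, None] - eta, -np.inf)
        cdf_u = np.where(np.isinf(upper), 1.0, 1.0 / (1.0 + np.exp(-np.clip(upper, -35, 35))))
        cdf_l = np.where(np.isneginf(lower), 0.0, 1.0 / (1.0 + np.exp(-np.clip(lower, -35, 35))))
        return np.log(np.clip(cdf_u - cdf_l, 1e-300, None))

    def objective(theta):
        kappa, beta, log_sigma = unpack(theta)
        ll = _marginal_loglik(lambda off: row_ll(off, kappa, beta), gidx, n_groups, n_quad)
        return -ll(log_sigma)

    res, se = _fit(objective, start, p)
    kappa, beta, log_sigma = unpack(res.x)
    return {
        "beta": beta,
        "se": se[K - 1 : K - 1 + p],
        "kappa": kappa,
        "sigma": float(np.exp(log_sigma)),
        "loglik": -float(res.fun),
        "n_obs": len(y),
        "n_groups": n_groups,
    }
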