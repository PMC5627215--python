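"""Negative-binomial GLMM with nested random intercepts, fitted by
Laplace-approximated maximum likelihood.

Model: y ~ NB2 with mean mu and shape k (variance mu * (1 + mu / k)),
log mu = X beta + u_trial + u_fish, u_trial ~ N(0, s2_trial),
u_fish ~ N(0, s2_fish), fish nested within trial.

The marginal likelihood integrates over the random effects; with only
intercept terms the integral is approximated by a Laplace expansion around
the joint mode of the random effects, found by an inner Newton iteration
(the penalised Hessian Z'WZ + D^-1 is positive definite, so plain Newton
with step halving is reliable).  The outer optimisation runs L-BFGS-B over
(beta, log s2_trial, log s2_fish, log k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["NBGLMMResult", "fit_nbglmm", "NBGLMMError"]

_LOG2PI = np.log(2.0 * np.pi)


class NBGLMMError(RuntimeError):
    """Fit failed (non-convergence or degenerate data)."""


@dataclass
class NBGLMMResult:
    beta: np.ndarray
    se: np.ndarray
    k: float
    sigma2_trial: float
    sigma2_fish: float
    loglik: float
    converged: bool
    n_obs: int
    exog_names: list

    def wald(self, idx: int) -> tuple[float, float]:
        """Wald z and two-sided p for one coefficient."""
        from scipy import stats

        z = self.beta[idx] / self.se[idx]
        return float(z), float(2 * stats.norm.sf(abs(z)))


def _nb_loglik_terms(y, eta, k):
    """Per-observation NB2 log-likelihood at linear predictor eta.

    eta is clipped to +-40 (far beyond any data scale here) so that wild
    intermediate steps of the optimisers cannot overflow exp.
    """
    mu = np.exp(np.clip(eta, -40.0, 40.0))
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )


def _inner_mode(y, Xb, k, trial_idx, fish_idx, J, K, s2t, s2f, b0, tol=1e-10):
    """Newton maximisation of the penalised log-likelihood over the random
    effects b = (u_trial, u_fish); returns (b_hat, f(b_hat), logdet H)."""
    b = b0.copy()
    fish_trial = np.zeros(K, dtype=int)
    fish_trial[fish_idx] = trial_idx  # each fish belongs to one trial

    def penalised(b):
        eta = Xb + b[trial_idx] + b[J + fish_idx]
        ll = _nb_loglik_terms(y, eta, k).sum()
        pen = (
            -0.5 * (b[:J] ** 2).sum() / s2t
            - 0.5 * J * (np.log(s2t) + _LOG2PI)
            - 0.5 * (b[J:] ** 2).sum() / s2f
            - 0.5 * K * (np.log(s2f) + _LOG2PI)
        )
        return ll + pen, eta

    f, eta = penalised(b)
    H = np.zeros((J + K, J + K))
    for _ in range(50):
        mu = np.exp(np.clip(eta, -40.0, 40.0))
        g_obs = y - (y + k) * mu / (mu + k)
        w = (y + k) * k * mu / (mu + k) ** 2
        grad = np.concatenate(
            [
                np.bincount(trial_idx, weights=g_obs, minlength=J) - b[:J] / s2t,
                np.bincount(fish_idx, weights=g_obs, minlength=K) - b[J:] / s2f,
            ]
        )
        wt = np.bincount(trial_idx, weights=w, minlength=J)
        wf = np.bincount(fish_idx, weights=w, minlength=K)
        H[:] = 0.0
        H[np.arange(J), np.arange(J)] = wt + 1.0 / s2t
        H[J + np.arange(K), J + np.arange(K)] = wf + 1.0 / s2f
        H[fish_trial, J + np.arange(K)] = wf
        H[J + np.arange(K), fish_trial] = wf
        step = np.linalg.solve(H, grad)
        if np.max(np.abs(grad)) < tol:
            break
        # step halving on the penalised objective
        alpha = 1.0
        for _ in range(30):
            b_new = b + alpha * step
            f_new, eta_new = penalised(b_new)
            if f_new >= f - 1e-12:
                break
            alpha *= 0.5
        if abs(f_new - f) < tol * (1 + abs(f)):
            b, f, eta = b_new, f_new, eta_new
            break
        b, f, eta = b_new, f_new, eta_new
    # recompute the Hessian at the final mode before taking its determinant
    mu = np.exp(np.clip(eta, -40.0, 40.0))
    w = (y + k) * k * mu / (mu + k) ** 2
    wt = np.bincount(trial_idx, weights=w, minlength=J)
    wf = np.bincount(fish_idx, weights=w, minlength=K)
    H[:] = 0.0
    H[np.arange(J), np.arange(J)] = wt + 1.0 / s2t
    H[J + np.arange(K), J + np.arange(K)] = wf + 1.0 / s2f
    H[fish_trial, J + np.arange(K)] = wf
    H[J + np.arange(K), fish_trial] = wf
    try:
        logdet = 2.0 * np.log(np.diag(np.linalg.cholesky(H))).sum()
    except np.linalg.LinAlgError as err:  # pragma: no cover - PD by construction
        raise NBGLMMError(f"penalised Hessian not positive definite: {err}")
    return b, f, logdet


def _laplace_nll(theta, y, X, trial_idx, fish_idx, J, K, warm):
    p = X.shape[1]
    beta = theta[:p]
    s2t = np.exp(theta[p])
    s2f = np.exp(theta[p + 1])
    k = np.exp(theta[p + 2])
    b, f, logdet = _inner_mode(
        y, X @ beta, k, trial_idx, fish_idx, J, K, s2t, s2f, warm["b"]
    )
    warm["b"] = b
    ll = f + 0.5 * (J + K) * _LOG2PI - 0.5 * logdet
    return -ll


def fit_nbglmm(
    y: np.ndarray,
    X: np.ndarray,
    trial_labels: np.ndarray,
    fish_labels: np.ndarray,
    exog_names: list | None = None,
    maxiter: int = 400,
) -> NBGLMMResult:
    """Fit the nested-intercept NB GLMM by Laplace ML.

    ``trial_labels`` and ``fish_labels`` are per-observation grouping labels
    (fish labels must be unique across trials).  Raises :class:`NBGLMMError`
    on non-convergence or degenerate input (e.g. an all-zero response).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise NBGLMMError("response must be non-negative integers")
    if np.all(y == 0):
        raise NBGLMMError("all-zero response: NB model degenerate")
    trials, trial_idx = np.unique(trial_labels, return_inverse=True)
    fish, fish_idx = np.unique(fish_labels, return_inverse=True)
    J, K = trials.size, fish.size
    p = X.shape[1]

    # moment-based starting values on the log scale
    lam = np.log(y.mean() + 0.5)
    beta0 = np.zeros(p)
    beta0[0] = lam
    vr = max(y.var() - y.mean(), 1e-3)
    k0 = float(np.clip(y.mean() ** 2 / vr, 0.05, 1e4))
    theta0 = np.concatenate([beta0, [np.log(0.05), np.log(0.05), np.log(k0)]])
    warm = {"b": np.zeros(J + K)}
    args = (y, X, trial_idx, fish_idx, J, K, warm)

    bounds = [(None, None)] * p + [
        (np.log(1e-8), np.log(1e4)),
        (np.log(1e-8), np.log(1e4)),
        (np.log(1e-4), np.log(1e6)),
    ]
    res = optimize.minimize(
        _laplace_nll,
        theta0,
        args=args,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise NBGLMMError(f"outer optimisation failed: {res.message}")
    theta = res.x
    nll = res.fun

    # observed-information SEs for beta via a finite-difference Hessian
    hess = _numeric_hessian(lambda t: _laplace_nll(t, *args), theta)
    se = np.full(p, np.nan)
    try:
        cov = np.linalg.inv(hess)
        dcov = np.diag(cov)[:p]
        if np.all(dcov > 0):
            se = np.sqrt(dcov)
    except np.linalg.LinAlgError:  # pragma: no cover - boundary fits
        pass
    return NBGLMMResult(
        beta=theta[:p],
        se=se,
        k=float(np.exp(theta[p + 2])),
        sigma2_trial=float(np.exp(theta[p])),
        sigma2_fish=float(np.exp(theta[p + 1])),
        loglik=float(-nll),
        converged=bool(res.success),
        n_obs=y.size,
        exog_names=list(exog_names) if exog_names is not None else [f"x{i}" for i in range(p)],
    )


def _numeric_hessian(fun, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H
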