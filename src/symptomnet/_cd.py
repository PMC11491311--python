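"""Numba kernels: L1 logistic regression paths and Gibbs sampling.

The coordinate-descent solver follows the glmnet scheme — an outer
iteratively-reweighted least-squares (IRLS) quadratic approximation with an
inner cyclic coordinate descent over the penalized weighted least-squares
problem — specialized to binary 0/1 predictors stored column-sparse (row
indices of the ones).  Predictors are not standardized and the intercept is
unpenalized; coefficients live on the log-odds scale throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# loss is scaled by 1/n: f(b0,b) = (1/n) sum_i [log(1+e^eta_i) - y_i eta_i] + lam * ||b||_1


@njit(cache=True)
def _cd_sweep(indptr, indices, n, w, r, eta, b, b0_box, lam, cap, included, only_active):
    """One cyclic sweep (intercept + slopes) on the weighted LS surrogate.

    Returns (max parameter change, number of coefficient caps applied).
    r holds the working residual z - eta; updating eta keeps r consistent.
    """
    m = b.shape[0]
    maxd = 0.0
    ncap = 0
    # intercept (unpenalized)
    num = 0.0
    den = 0.0
    for i in range(n):
        num += w[i] * r[i]
        den += w[i]
    d0 = num / den
    if d0 != 0.0:
        b0_box[0] += d0
        for i in range(n):
            r[i] -= d0
            eta[i] += d0
        if abs(d0) > maxd:
            maxd = abs(d0)
    for j in range(m):
        if not included[j]:
            continue
        if only_active and b[j] == 0.0:
            continue
        s = indptr[j]
        e = indptr[j + 1]
        rho = 0.0
        aj = 0.0
        for k in range(s, e):
            i = indices[k]
            rho += w[i] * r[i]
            aj += w[i]
        if aj <= 0.0:
            continue
        rho = rho / n + (aj / n) * b[j]
        ajn = aj / n
        if rho > lam:
            bj = (rho - lam) / ajn
        elif rho < -lam:
            bj = (rho + lam) / ajn
        else:
            bj = 0.0
        if bj > cap:
            bj = cap
            ncap += 1
        elif bj < -cap:
            bj = -cap
            ncap += 1
        d = bj - b[j]
        if d != 0.0:
            b[j] = bj
            for k in range(s, e):
                i = indices[k]
                r[i] -= d
                eta[i] += d
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd, ncap


@njit(cache=True)
def _reweight(y, eta, w, r, n):
    """Refresh IRLS weights and working residual at the current eta."""
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            pe = 1.0 / (1.0 + np.exp(-e))
        else:
            ex = np.exp(e)
            pe = ex / (1.0 + ex)
        wi = pe * (1.0 - pe)
        if wi < 1e-6:
            wi = 1e-6
        w[i] = wi
        r[i] = (y[i] - pe) / wi


@njit(cache=True)
def _loglik(y, eta, n):
    ll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 35.0:
            lse = e
        elif e < -35.0:
            lse = 0.0
        else:
            lse = np.log1p(np.exp(e))
        ll += y[i] * e - lse
    return ll


@njit(cache=True)
def logistic_path(indptr, indices, n, m, y, included, lambdas, b0_init, tol, max_sweeps, cap):
    """Solve the L1 logistic path over a decreasing lambda grid (warm starts).

    Returns (intercepts, coefs[L, m], logliks[L], n_capped[L]).
    """
    L = lambdas.shape[0]
    b0s = np.zeros(L)
    coefs = np.zeros((L, m))
    logliks = np.zeros(L)
    ncaps = np.zeros(L, np.int64)
    b = np.zeros(m)
    b0_box = np.zeros(1)
    b0_box[0] = b0_init
    eta = np.full(n, b0_init)
    w = np.empty(n)
    r = np.empty(n)
    for li in range(L):
        lam = lambdas[li]
        ncap_total = 0
        sweeps_left = max_sweeps
        while sweeps_left > 0:
            _reweight(y, eta, w, r, n)
            # full sweep doubles as the outer convergence / KKT check
            maxd, nc = _cd_sweep(
                indptr, indices, n, w, r, eta, b, b0_box, lam, cap, included, False
            )
            ncap_total += nc
            sweeps_left -= 1
            if maxd < tol:
                break
            # a short burst of active-set sweeps on the current quadratic;
            # reweighting often (proximal Newton) beats solving it exactly
            burst = 0
            while burst < 5 and sweeps_left > 0:
                maxd, nc = _cd_sweep(
                    indptr, indices, n, w, r, eta, b, b0_box, lam, cap, included, True
                )
                ncap_total += nc
                sweeps_left -= 1
                burst += 1
                if maxd < tol:
                    break
        b0s[li] = b0_box[0]
        for j in range(m):
            # snap numerical residue (far below the convergence tolerance)
            # to exact zero so support counts stay meaningful
            coefs[li, j] = b[j] if abs(b[j]) > 1e-10 else 0.0
        logliks[li] = _loglik(y, eta, n)
        ncaps[li] = ncap_total
    return b0s, coefs, logliks, ncaps


@njit(cache=True)
def gibbs_sample(tau, weights, n_samples, burn_in, thin, seed):
    """Single-site Gibbs sampler with a fixed 0..p-1 scan order.

    Draws ``n_samples`` configurations, keeping every ``thin``-th sweep after
    ``burn_in`` sweeps; reproducible given the integer seed.
    """
    np.random.seed(seed)
    p = tau.shape[0]
    x = np.zeros(p, np.float64)
    # start from the independent-node distribution
    for i in range(p):
        pi = 1.0 / (1.0 + np.exp(-tau[i]))
        if np.random.random() < pi:
            x[i] = 1.0
    out = np.empty((n_samples, p), np.int8)
    total = burn_in + n_samples * thin
    kept = 0
    for sweep in range(total):
        for i in range(p):
            eta = tau[i]
            for j in range(p):
                eta += weights[i, j] * x[j]  # diagonal is zero
            pi = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1.0 if np.random.random() < pi else 0.0
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            for j in range(p):
                out[kept, j] = np.int8(x[j])
            kept += 1
            if kept == n_samples:
                break
    return out
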