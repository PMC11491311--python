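"""Independent cross-checks and benchmark constructions.

These utilities deliberately avoid the package's own solver paths so they
can serve as oracles: the reference L1 objective is minimized by scipy's
L-BFGS-B on the smooth bound-constrained split ``b = b+ - b-``, and the
goodness-of-fit helper compares sampled configuration counts against the
exactly enumerated joint pmf.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .ising import IsingNetwork, exact_pmf

__all__ = [
    "l1_reference_fit",
    "chisquare_gof",
    "support_metrics",
    "recovery_benchmark_network",
    "equal_edges_network",
    "stability_benchmark_network",
]


def l1_reference_fit(y: np.ndarray, X: np.ndarray, lam: float) -> tuple[float, np.ndarray, float]:
    """Reference minimizer of the L1-penalized logistic objective.

    Splits each slope into positive and negative parts, turning
    ``(1/n) nll + lam ||b||_1`` into a smooth problem over non-negative
    variables solved by L-BFGS-B with an analytic gradient.  Returns
    (intercept, slopes, objective value).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape

    def fun(theta):
        b0, bp, bm = theta[0], theta[1 : 1 + m], theta[1 + m :]
        b = bp - bm
        eta = b0 + X @ b
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        f = (np.sum(np.logaddexp(0.0, eta)) - y @ eta) / n + lam * (bp.sum() + bm.sum())
        resid = (p - y) / n
        g0 = resid.sum()
        gb = X.T @ resid
        return f, np.concatenate(([g0], gb + lam, -gb + lam))

    x0 = np.zeros(1 + 2 * m)
    bounds = [(None, None)] + [(0, None)] * (2 * m)
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    b = res.x[1 : 1 + m] - res.x[1 + m :]
    return float(res.x[0]), b, float(res.fun)


def chisquare_gof(sample: np.ndarray, net: IsingNetwork, min_expected: float = 5.0) -> float:
    """Chi-square goodness-of-fit p-value of sampled configurations vs the
    exact joint pmf, pooling low-expectation cells (p <= 16)."""
    sample = np.asarray(sample)
    n, p = sample.shape
    codes = (sample.astype(np.int64) * (1 << np.arange(p))).sum(axis=1)
    obs = np.bincount(codes, minlength=2**p).astype(float)
    exp = exact_pmf(net) * n
    order = np.argsort(exp)
    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for c in order:
        acc_o += obs[c]
        acc_e += exp[c]
        if acc_e >= min_expected:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if merged_e:
        merged_o[-1] += acc_o
        merged_e[-1] += acc_e
    merged_e = np.asarray(merged_e) * (np.sum(merged_o) / np.sum(merged_e))
    return float(stats.chisquare(merged_o, merged_e).pvalue)


def support_metrics(true_weights: np.ndarray, est_weights: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) of the recovered edge support."""
    iu = np.triu_indices(true_weights.shape[0], 1)
    t = true_weights[iu] != 0
    e = est_weights[iu] != 0
    tp = int((t & e).sum())
    fn = int((t & ~e).sum())
    fp = int((~t & e).sum())
    tn = int((~t & ~e).sum())
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec


def _net(p: int, edges, tau: float = -1.0) -> IsingNetwork:
    w = np.zeros((p, p))
    for a, b, v in edges:
        w[a, b] = w[b, a] = v
    return IsingNetwork(np.full(p, tau), w, tuple(f"N{i}" for i in range(p)))


def recovery_benchmark_network() -> IsingNetwork:
    """p = 10 sparse ground truth with 6 edges, |beta| in [0.8, 1.5]."""
    return _net(
        10,
        [(0, 1, 1.2), (2, 3, 0.9), (4, 5, 1.5), (6, 7, -0.8), (8, 9, 1.1), (1, 4, 0.85)],
    )


def equal_edges_network(beta: float = 1.0) -> IsingNetwork:
    """p = 6 network with two exchangeable equal couplings (0-1 and 2-3)."""
    return _net(6, [(0, 1, beta), (2, 3, beta)], tau=-0.5)


def stability_benchmark_network() -> IsingNetwork:
    """p = 12 well-determined ring-plus-blocks network for case-dropping runs."""
    return _net(
        12,
        [(0, 1, 1.3), (1, 2, 1.1), (2, 3, 1.2), (3, 4, 1.0), (4, 5, 1.3), (5, 0, 1.1),
         (6, 7, 1.2), (8, 9, 1.0), (10, 11, 1.2), (0, 6, 0.9)],
    )
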