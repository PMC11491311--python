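"""eLASSO estimation of an Ising network.

For every node, an L1-penalized logistic regression of that node on all
others is solved over a decreasing lambda grid; the extended Bayesian
information criterion (EBIC) picks one model per node; the AND (or OR) rule
symmetrizes the two directed coefficients of each pair into an undirected
edge weight.  Thresholds are the selected intercepts.

Conventions (configurable): 100 log-spaced lambdas from the analytic
per-node lambda_max down to 0.01 * lambda_max; predictors unstandardized;
equal-EBIC ties resolved toward the sparser (larger-lambda) model; AND-rule
edge weight = arithmetic mean of the two nodewise slopes; coefficients
capped at |b| <= 15 with a warning when separation pushes them off to
infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._cd import logistic_path
from .data_model import BinaryMatrix
from .ising import IsingNetwork

__all__ = [
    "RegularizationPath",
    "FitResult",
    "ebic",
    "l1_logistic_path",
    "select_per_node",
    "symmetrize",
    "fit_ising",
    "penalized_objective",
]

DEFAULT_GAMMA = 0.25
DEFAULT_RULE = "AND"
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01
DEFAULT_TOL = 1e-7
DEFAULT_MAX_SWEEPS = 10_000
COEF_CAP = 15.0


@dataclass(frozen=True)
class RegularizationPath:
    """Per-node record of the lambda grid, coefficient paths and EBIC values."""

    node_index: int
    node_label: str
    predictor_labels: tuple[str, ...]
    lambdas: np.ndarray  # strictly decreasing
    intercepts: np.ndarray  # (L,)
    coefficients: np.ndarray  # (L, p-1)
    logliks: np.ndarray  # (L,)
    nonzero_counts: np.ndarray  # (L,)
    ebic_values: np.ndarray  # (L,)
    gamma: float
    selected_index: int
    n_capped: int = 0

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected_index])

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficients[self.selected_index]


@dataclass(frozen=True)
class FitResult:
    """An estimated Ising network with its per-node model-selection record."""

    network: IsingNetwork
    paths: tuple[RegularizationPath, ...]
    rule: str
    gamma: float
    nodewise_slopes: np.ndarray = field(repr=False)  # (p, p), row i = regression of node i
    warnings_: tuple[str, ...] = ()


def ebic(loglik: float, k: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2*loglik + k*log(n) + 2*gamma*k*log(p-1).

    ``k`` is the number of nonzero slopes (neighbours) of the node's model and
    ``p`` the number of nodes in the network, so p-1 candidate predictors.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 2:
        raise ValueError("p must be >= 2")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p - 1)


def _as_binary_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr


def _csc_binary(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-sparse row indices of the ones of a binary matrix."""
    cols = [np.flatnonzero(X[:, j]).astype(np.int64) for j in range(X.shape[1])]
    indptr = np.zeros(X.shape[1] + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([c.size for c in cols])
    indices = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    return indptr, indices


def lambda_max(X: np.ndarray, y: np.ndarray, included: np.ndarray | None = None) -> float:
    """Smallest lambda with an all-zero slope vector: max_j |X_j'(y - ybar)| / n."""
    n = y.shape[0]
    g = np.abs(X.T @ (y - y.mean())) / n
    if included is not None:
        g = g[included]
    return float(g.max()) if g.size else 0.0


def make_lambda_grid(
    lam_max: float,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    if lam_max <= 0:
        lam_max = 1e-4  # degenerate node: y uncorrelated with every predictor
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def l1_logistic_path(
    y,
    X,
    lambda_grid: np.ndarray | None = None,
    *,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    cap: float = COEF_CAP,
    node_label: str = "y",
) -> dict:
    """L1-penalized logistic coefficient paths over a decreasing lambda grid.

    The intercept is unpenalized and predictors enter unstandardized.  Constant
    predictor columns get forced-zero coefficients and a warning.  Returns a
    dict with lambdas, intercepts, coefficients, logliks, nonzero counts and
    the capped-update count.
    """
    y = _as_binary_array(y, "y")
    X = _as_binary_array(X, "X")
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X row counts differ")
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError(f"node {node_label!r} takes a single value; cannot regress")
    included = np.ones(m, dtype=np.bool_)
    col_means = X.mean(axis=0)
    const = (col_means == 0.0) | (col_means == 1.0)
    if const.any():
        warnings.warn(
            f"constant predictor columns forced to zero for node {node_label!r}: "
            f"{np.flatnonzero(const).tolist()}",
            stacklevel=2,
        )
        included[const] = False
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(lambda_max(X, y, included), n_lambda, lambda_min_ratio)
    lambda_grid = np.asarray(lambda_grid, dtype=np.float64)
    if lambda_grid.ndim != 1 or lambda_grid.size == 0:
        raise ValueError("lambda grid must be a nonempty 1-D array")
    if lambda_grid.size > 1 and not (np.diff(lambda_grid) < 0).all():
        raise ValueError("lambda grid must be strictly decreasing")
    if (lambda_grid <= 0).any():
        raise ValueError("lambdas must be positive")
    indptr, indices = _csc_binary(X)
    b0_init = float(np.log(ybar / (1.0 - ybar)))
    b0s, coefs, logliks, ncaps = logistic_path(
        indptr, indices, n, m, y, included, lambda_grid, b0_init, tol, max_sweeps, cap
    )
    n_capped = int(ncaps.sum())
    if n_capped:
        warnings.warn(
            f"separation guard: {n_capped} coefficient update(s) capped at |b|={cap} "
            f"for node {node_label!r}",
            stacklevel=2,
        )
    return {
        "lambdas": lambda_grid,
        "intercepts": b0s,
        "coefficients": coefs,
        "logliks": logliks,
        "nonzero_counts": np.count_nonzero(coefs, axis=1),
        "n_capped": n_capped,
    }


def penalized_objective(b0: float, b: np.ndarray, y: np.ndarray, X: np.ndarray, lam: float) -> float:
    """(1/n) * negative log-likelihood + lam * ||b||_1 (intercept unpenalized)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    eta = b0 + X @ np.asarray(b, dtype=float)
    nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta) / y.shape[0]
    return nll + lam * float(np.abs(b).sum())


def select_per_node(path: RegularizationPath | dict) -> int:
    """Index of the EBIC-minimizing lambda; ties go to the larger lambda.

    The grid is decreasing, so ``argmin`` (first minimum) realizes the
    sparser-model tie rule.
    """
    ebics = path.ebic_values if isinstance(path, RegularizationPath) else path["ebic_values"]
    return int(np.argmin(ebics))


def symmetrize(slopes: np.ndarray, rule: str = DEFAULT_RULE) -> np.ndarray:
    """Combine nodewise slopes into symmetric edge weights.

    AND: weight = mean(b_ij, b_ji) when both are nonzero, else 0.
    OR:  weight = mean(b_ij, b_ji) when at least one is nonzero.
    """
    b = np.asarray(slopes, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError("slope matrix must be square")
    if np.any(np.diag(b) != 0.0):
        raise ValueError("slope matrix must have a zero diagonal")
    mean = (b + b.T) / 2.0
    if rule.upper() == "AND":
        mask = (b != 0.0) & (b.T != 0.0)
    elif rule.upper() == "OR":
        mask = (b != 0.0) | (b.T != 0.0)
    else:
        raise ValueError(f"unknown symmetrization rule: {rule!r}")
    return np.where(mask, mean, 0.0)


def fit_ising(
    data: BinaryMatrix,
    gamma: float = DEFAULT_GAMMA,
    rule: str = DEFAULT_RULE,
    *,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    cap: float = COEF_CAP,
) -> FitResult:
    """Estimate an Ising network from a binary matrix by eLASSO.

    Deterministic given the data and settings; invariant to row order.
    Raises if any column is constant (the caller must drop or regenerate).
    """
    if not isinstance(data, BinaryMatrix):
        data = BinaryMatrix(np.asarray(data), tuple(f"V{i}" for i in range(np.asarray(data).shape[1])))
    X_all = data.values.astype(np.float64)
    n, p = X_all.shape
    labels = data.node_labels
    col_means = X_all.mean(axis=0)
    constant = [labels[j] for j in np.flatnonzero((col_means == 0.0) | (col_means == 1.0))]
    if constant:
        raise ValueError(f"constant columns (drop or regenerate): {constant}")
    fit_warnings: list[str] = []
    if n < p:
        msg = f"n={n} < p={p}: estimates may be unstable"
        warnings.warn(msg, stacklevel=2)
        fit_warnings.append(msg)
    slopes = np.zeros((p, p))
    intercepts = np.zeros(p)
    paths: list[RegularizationPath] = []
    rest_idx = [np.array([j for j in range(p) if j != i]) for i in range(p)]
    for i in range(p):
        idx = rest_idx[i]
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            res = l1_logistic_path(
                X_all[:, i],
                X_all[:, idx],
                n_lambda=n_lambda,
                lambda_min_ratio=lambda_min_ratio,
                tol=tol,
                max_sweeps=max_sweeps,
                cap=cap,
                node_label=labels[i],
            )
        for w in wrec:
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
            fit_warnings.append(str(w.message))
        ebics = np.array(
            [
                ebic(ll, int(k), n, p, gamma)
                for ll, k in zip(res["logliks"], res["nonzero_counts"])
            ]
        )
        sel = int(np.argmin(ebics))
        path = RegularizationPath(
            node_index=i,
            node_label=labels[i],
            predictor_labels=tuple(labels[j] for j in idx),
            lambdas=res["lambdas"],
            intercepts=res["intercepts"],
            coefficients=res["coefficients"],
            logliks=res["logliks"],
            nonzero_counts=res["nonzero_counts"],
            ebic_values=ebics,
            gamma=gamma,
            selected_index=sel,
            n_capped=res["n_capped"],
        )
        paths.append(path)
        intercepts[i] = path.selected_intercept
        slopes[i, idx] = path.selected_coefficients
    weights = symmetrize(slopes, rule)
    network = IsingNetwork(intercepts, weights, labels)
    return FitResult(
        network=network,
        paths=tuple(paths),
        rule=rule.upper(),
        gamma=gamma,
        nodewise_slopes=slopes,
        warnings_=tuple(fit_warnings),
    )
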