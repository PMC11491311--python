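"""Bootstrap accuracy and stability of the estimated network.

Three procedures, following the standard accuracy toolbox for
psychological networks:

* nonparametric (row-resampling) bootstrap of edge weights, with
  percentile confidence intervals;
* bootstrapped difference tests for pairs of edge weights or node
  strengths (significant when the bootstrap interval of the difference
  excludes zero);
* case-dropping subset bootstrap for the stability of the strength
  order, summarized by the correlation-stability (CS) coefficient: the
  largest drop proportion at which the subset-vs-full strength
  correlation stays >= 0.7 with probability >= 0.95.

All resampling is reproducible: replicate r of a run with master seed s
uses ``numpy`` generator ``default_rng([s, stream, r, attempt])``, so
results are independent of execution order or worker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .centrality import strength_vector
from .data_model import BinaryMatrix
from .elasso import DEFAULT_GAMMA, DEFAULT_RULE, FitResult, fit_ising
from .ising import IsingNetwork

__all__ = [
    "BootstrapEnsemble",
    "StabilityResult",
    "edge_ci_bootstrap",
    "difference_test",
    "case_dropping",
    "cs_coefficient",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.7501, 0.05), 2))
CS_CORRELATION_THRESHOLD = 0.7
CS_PROBABILITY_THRESHOLD = 0.95
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Per-replicate networks from a row-resampling bootstrap."""

    networks: tuple[IsingNetwork, ...]
    full_fit: FitResult
    scheme: str  # rows_with_replacement | case_dropping
    seed: int
    gamma: float
    rule: str
    n_redrawn: int = 0

    @property
    def B(self) -> int:
        return len(self.networks)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.full_fit.network.node_labels

    def edge_replicates(self, pairs: list[tuple[int, int]]) -> np.ndarray:
        """(n_pairs, B) matrix of replicate edge weights."""
        return np.array(
            [[net.weights[i, j] for net in self.networks] for i, j in pairs]
        )

    def strength_replicates(self, signed: bool = False) -> np.ndarray:
        """(p, B) matrix of replicate node strengths."""
        return np.array([strength_vector(net, signed) for net in self.networks]).T


@dataclass(frozen=True)
class StabilityResult:
    """Case-dropping correlations between subset and full-sample strength."""

    drop_proportions: tuple[float, ...]
    correlations: np.ndarray  # (n_proportions, B); NaN = failed replicate
    correlation_threshold: float = CS_CORRELATION_THRESHOLD
    probability_threshold: float = CS_PROBABILITY_THRESHOLD
    skipped_proportions: tuple[float, ...] = ()
    seed: int = 0

    def qualifying(self) -> np.ndarray:
        """Per proportion: does P(corr >= threshold) >= probability_threshold hold?"""
        ok = np.zeros(len(self.drop_proportions), dtype=bool)
        for k, _ in enumerate(self.drop_proportions):
            row = self.correlations[k]
            row = row[~np.isnan(row)]
            if row.size == 0:
                continue
            ok[k] = (row >= self.correlation_threshold).mean() >= self.probability_threshold
        return ok

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drop_proportion": self.drop_proportions,
                "mean_correlation": np.nanmean(self.correlations, axis=1),
                "p_above_threshold": [
                    np.mean(row[~np.isnan(row)] >= self.correlation_threshold)
                    if (~np.isnan(row)).any()
                    else np.nan
                    for row in self.correlations
                ],
            }
        )


def _rng(seed: int, stream: int, rep: int, attempt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(rep), int(attempt)])


def _has_constant_column(values: np.ndarray) -> bool:
    m = values.mean(axis=0)
    return bool(((m == 0.0) | (m == 1.0)).any())


def edge_ci_bootstrap(
    data: BinaryMatrix,
    B: int = 1000,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    rule: str = DEFAULT_RULE,
    ci: float = 0.95,
    **fit_kwargs,
) -> tuple[pd.DataFrame, BootstrapEnsemble]:
    """Row-resampling bootstrap of edge weights with percentile CIs.

    Each replicate resamples n rows with replacement and refits with the
    same settings; a replicate that produces a constant column is redrawn
    (and counted in the ensemble).  Quantiles use the default linear
    (type-7) interpolation.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    full_fit = fit_ising(data, gamma=gamma, rule=rule, **fit_kwargs)
    n = data.n
    nets: list[IsingNetwork] = []
    n_redrawn = 0
    for b in range(B):
        for attempt in range(_MAX_REDRAWS):
            rows = _rng(seed, 0, b, attempt).integers(0, n, size=n)
            vals = data.values[rows]
            if _has_constant_column(vals):
                n_redrawn += 1
                continue
            rep = fit_ising(BinaryMatrix(vals, data.node_labels), gamma=gamma, rule=rule, **fit_kwargs)
            nets.append(rep.network)
            break
        else:
            raise RuntimeError(f"replicate {b}: could not draw a non-degenerate resample")
    ensemble = BootstrapEnsemble(
        networks=tuple(nets),
        full_fit=full_fit,
        scheme="rows_with_replacement",
        seed=seed,
        gamma=gamma,
        rule=rule,
        n_redrawn=n_redrawn,
    )
    labels = data.node_labels
    p = data.p
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    reps = ensemble.edge_replicates(pairs)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    table = pd.DataFrame(
        {
            "node_a": [labels[i] for i, _ in pairs],
            "node_b": [labels[j] for _, j in pairs],
            "estimate": [full_fit.network.weights[i, j] for i, j in pairs],
            "boot_mean": reps.mean(axis=1),
            "ci_lower": np.quantile(reps, lo_q, axis=1),
            "ci_upper": np.quantile(reps, hi_q, axis=1),
        }
    )
    return table, ensemble


def difference_test(
    ensemble: BootstrapEnsemble,
    quantity: str = "edge",
    alpha: float = 0.05,
    items: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Bootstrapped difference test between pairs of edges or strengths.

    A pair (a, b) is flagged significant when the bootstrap
    [alpha/2, 1-alpha/2] interval of value_a - value_b excludes zero.
    For ``quantity="edge"`` the items default to the edges that are nonzero
    in the full-sample network.  Returns the symmetric boolean significance
    matrix (diagonal False) and item labels.
    """
    if ensemble.B < 2:
        raise ValueError("ensemble must contain at least 2 replicates")
    labels = ensemble.labels
    if quantity == "edge":
        if items is None:
            w = ensemble.full_fit.network.weights
            items = [
                (i, j)
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
                if w[i, j] != 0.0
            ]
        values = ensemble.edge_replicates(items)
        names = [f"{labels[i]}--{labels[j]}" for i, j in items]
    elif quantity == "strength":
        values = ensemble.strength_replicates()
        names = list(labels)
    else:
        raise ValueError(f"unknown quantity: {quantity!r}")
    k = values.shape[0]
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            d = values[a] - values[b]
            lo, hi = np.quantile(d, [alpha / 2, 1 - alpha / 2])
            sig[a, b] = sig[b, a] = (lo > 0) or (hi < 0)
    return sig, names


def case_dropping(
    data: BinaryMatrix,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    rule: str = DEFAULT_RULE,
    correlation: str = "spearman",
    **fit_kwargs,
) -> StabilityResult:
    """Case-dropping subset bootstrap of the strength order.

    For each drop proportion q, B subsamples of floor((1-q)*n) rows are
    drawn without replacement, the network refitted, and the subset strength
    vector Spearman-correlated with the full-sample strength.  Proportions
    whose subsets are too small to fit are skipped with a warning.
    """
    if correlation != "spearman":
        raise ValueError("only spearman correlation is supported")
    if any(not (0 <= q < 1) for q in proportions):
        raise ValueError("drop proportions must lie in [0, 1)")
    full_fit = fit_ising(data, gamma=gamma, rule=rule, **fit_kwargs)
    s_full = strength_vector(full_fit.network)
    n = data.n
    kept_props: list[float] = []
    skipped: list[float] = []
    rows_corr: list[np.ndarray] = []
    for k, q in enumerate(proportions):
        n_keep = int(np.floor((1 - q) * n))
        if n_keep < 3:
            warnings.warn(f"drop proportion {q}: subset of {n_keep} rows too small; skipped")
            skipped.append(q)
            continue
        corr = np.full(B, np.nan)
        for b in range(B):
            if q == 0:
                sub_vals = data.values
            else:
                for attempt in range(_MAX_REDRAWS):
                    rows = _rng(seed, k + 1, b, attempt).choice(n, size=n_keep, replace=False)
                    sub_vals = data.values[rows]
                    if not _has_constant_column(sub_vals):
                        break
                else:
                    continue  # leave NaN
            sub_fit = fit_ising(BinaryMatrix(sub_vals, data.node_labels), gamma=gamma, rule=rule, **fit_kwargs)
            s_sub = strength_vector(sub_fit.network)
            if np.ptp(s_sub) == 0 or np.ptp(s_full) == 0:
                # a constant strength vector has no rank order; count as failure
                corr[b] = 1.0 if np.array_equal(s_sub, s_full) else 0.0
            else:
                corr[b] = spearmanr(s_sub, s_full).statistic
        kept_props.append(float(q))
        rows_corr.append(corr)
    return StabilityResult(
        drop_proportions=tuple(kept_props),
        correlations=np.array(rows_corr) if rows_corr else np.zeros((0, B)),
        skipped_proportions=tuple(skipped),
        seed=seed,
    )


def cs_coefficient(result: StabilityResult) -> float:
    """Correlation-stability coefficient.

    The largest drop proportion q such that the qualifying rule
    (P(corr >= 0.7) >= 0.95) holds at q and at every smaller proportion in
    the grid; 0 when no proportion qualifies.  Bounded above by the grid
    maximum (0.75 on the default grid).
    """
    if len(result.drop_proportions) == 0:
        raise ValueError("stability grid is empty")
    order = np.argsort(result.drop_proportions)
    ok = result.qualifying()
    cs = 0.0
    for k in order:
        if ok[k]:
            cs = float(result.drop_proportions[k])
        else:
            break
    return cs
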