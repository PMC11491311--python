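"""The Ising model over binary symptom variables.

A network is parameterized by node thresholds tau (log-odds scale) and a
symmetric zero-diagonal coupling matrix beta, with joint pmf

    P(x) = exp( sum_i tau_i x_i + sum_{i<j} beta_ij x_i x_j ) / Z,   x in {0,1}^p.

The conditional of one node given the rest is logistic in the active
neighbours, which is what makes nodewise logistic regression a consistent
estimation route.  Variables are coded {0,1}; the affine map to {-1,+1}
spin coding is documented in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "IsingNetwork",
    "conditional_probability",
    "joint_logpmf_exact",
    "log_partition",
    "pseudo_loglik",
    "enumerate_states",
]

_ENUM_LIMIT = 20  # 2^p state enumeration cap


@dataclass(frozen=True)
class IsingNetwork:
    """Thresholds, symmetric couplings and node labels of an Ising network."""

    thresholds: np.ndarray  # (p,)
    weights: np.ndarray  # (p, p) symmetric, zero diagonal
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        p = tau.shape[0]
        if w.shape != (p, p):
            raise ValueError("weights must be p x p")
        if len(self.node_labels) != p:
            raise ValueError("label count must equal p")
        if not (np.isfinite(tau).all() and np.isfinite(w).all()):
            raise ValueError("parameters must be finite")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0, atol=1e-12):
            raise ValueError("weights must have a zero diagonal")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "thresholds", tau)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def p(self) -> int:
        return self.thresholds.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    out.append((self.node_labels[i], self.node_labels[j], float(self.weights[i, j])))
        return out

    def permute(self, order: np.ndarray) -> "IsingNetwork":
        order = np.asarray(order)
        return IsingNetwork(
            self.thresholds[order],
            self.weights[np.ix_(order, order)],
            tuple(self.node_labels[i] for i in order),
        )

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "labels": list(self.node_labels),
                "thresholds": self.thresholds.tolist(),
                "weights": self.weights.tolist(),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "IsingNetwork":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(np.array(d["thresholds"]), np.array(d["weights"]), tuple(d["labels"]))

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, w in self.edges():
                fh.write(f"{a}\t{b}\t{w:.10g}\n")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for lab, tau in zip(self.node_labels, self.thresholds):
            g.add_node(lab, threshold=float(tau))
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w)
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def conditional_probability(net: IsingNetwork, i: int, x: np.ndarray) -> float:
    """P(X_i = 1 | rest) = logistic(tau_i + sum_{j != i} beta_ij x_j)."""
    if not 0 <= i < net.p:
        raise IndexError(f"node index {i} out of range for p={net.p}")
    x = np.asarray(x, dtype=float)
    eta = net.thresholds[i] + net.weights[i] @ x  # diagonal is zero, x_i drops out
    return float(expit(eta))


def enumerate_states(p: int) -> np.ndarray:
    """All 2^p binary configurations, row c = bits of c (LSB = node 0)."""
    if p > _ENUM_LIMIT:
        raise ValueError(
            f"p={p} too large for exact enumeration (max {_ENUM_LIMIT}); "
            "use the Gibbs sampler"
        )
    codes = np.arange(2**p, dtype=np.int64)
    return ((codes[:, None] >> np.arange(p)) & 1).astype(np.float64)


def _unnormalized_logweights(net: IsingNetwork) -> np.ndarray:
    states = enumerate_states(net.p)
    return states @ net.thresholds + 0.5 * np.einsum("ci,ij,cj->c", states, net.weights, states)


def log_partition(net: IsingNetwork) -> float:
    """log Z by exhaustive enumeration (p <= 20)."""
    return float(logsumexp(_unnormalized_logweights(net)))


def joint_logpmf_exact(net: IsingNetwork, x: np.ndarray) -> float:
    """Exact normalized log P(x); requires p <= 20."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.p,):
        raise ValueError("configuration length must equal p")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("configuration entries must be binary")
    logw = x @ net.thresholds + 0.5 * x @ net.weights @ x
    return float(logw - log_partition(net))


def exact_pmf(net: IsingNetwork) -> np.ndarray:
    """Probability of every configuration, ordered as ``enumerate_states``."""
    logw = _unnormalized_logweights(net)
    return np.exp(logw - logsumexp(logw))


def exact_marginals(net: IsingNetwork) -> np.ndarray:
    """Exact P(X_i = 1) per node by enumeration (p <= 20)."""
    return exact_pmf(net) @ enumerate_states(net.p)


def pseudo_loglik(net: IsingNetwork, data) -> float:
    """Sum over rows and nodes of the conditional log-likelihoods.

    This is the log pseudo-likelihood that nodewise logistic regression
    maximizes in aggregate; always <= 0.
    """
    values = data.values if hasattr(data, "values") else np.asarray(data)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != net.p:
        raise ValueError("data dimension does not match network")
    if hasattr(data, "node_labels") and tuple(data.node_labels) != net.node_labels:
        raise ValueError("data labels do not match network labels")
    eta = net.thresholds[None, :] + values @ net.weights  # (n, p)
    return float(np.sum(values * eta) - np.sum(np.logaddexp(0.0, eta)))
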