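"""Strength centrality: per-node sum of incident edge-weight magnitudes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ising import IsingNetwork

__all__ = ["strength", "strength_vector"]


def strength_vector(net: IsingNetwork, signed: bool = False) -> np.ndarray:
    """Strength per node: sum_j |beta_ij| (or the signed sum, the
    "expected influence" variant, when ``signed=True``)."""
    w = net.weights if signed else np.abs(net.weights)
    return w.sum(axis=1)


def strength(net: IsingNetwork, signed: bool = False) -> pd.DataFrame:
    """Strength centrality table (label, strength, rank).

    Ranks are 1..p by decreasing strength; ties are broken by node (label)
    order so the ranking is a deterministic permutation.
    """
    s = strength_vector(net, signed=signed)
    order = np.lexsort((np.arange(net.p), -s))  # stable: ties keep label order
    rank = np.empty(net.p, dtype=int)
    rank[order] = np.arange(1, net.p + 1)
    return pd.DataFrame(
        {"label": list(net.node_labels), "strength": s, "rank": rank}
    )
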