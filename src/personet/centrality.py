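"""Centrality indices for directed weighted personal symptom networks.

In-strength of a node is the sum of absolute weights of edges pointing to
it; out-strength the sum of absolute weights of edges pointing out of it.
Absolute values are used because estimated log-odds edges can be negative;
self-loops (symptom persistence) are excluded — they represent persistence,
not inter-symptom brokerage.  Betweenness counts, fractionally over tied
shortest paths, how often a node lies on the shortest path between two
other nodes, with edge distances 1/|weight|.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model_core import PersonalNetwork

__all__ = ["strength_centralities", "betweenness", "spearman_correlation",
           "centrality_table", "METRICS"]

METRICS = ("in_strength", "out_strength", "betweenness")


def _weights(network) -> np.ndarray:
    W = network.weights if isinstance(network, PersonalNetwork) \
        else np.asarray(network, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.isfinite(W).all():
        raise ValueError("weights must be finite")
    return W


def strength_centralities(network, exclude_self: bool = True):
    """Per-node (in_strength, out_strength) from absolute edge weights.

    W[j, j'] is the edge j' -> j, so in-strength of node j sums |row j| and
    out-strength of node j' sums |column j'|.
    """
    W = np.abs(_weights(network))
    if exclude_self:
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    return W.sum(axis=1), W.sum(axis=0)


def betweenness(network) -> np.ndarray:
    """Directed shortest-path betweenness with distances 1/|weight|.

    Brandes accumulation: each of the tied shortest paths between a source
    and target contributes equally.  Self-loops are ignored; unreachable
    pairs contribute nothing.
    """
    W = _weights(network)
    p = W.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(p))
    rows, cols = np.nonzero(W)
    for j, k in zip(rows, cols):
        if j != k:
            g.add_edge(k, j, distance=1.0 / abs(W[j, k]))
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return np.array([bc[j] for j in range(p)])


def spearman_correlation(a, b) -> float:
    """Spearman rank correlation via Pearson correlation of mid-ranks.

    Ties get average ranks.  If either vector has zero variance no rank
    information is preserved; such comparisons return 0.0 by convention
    (conservative for stability summaries of networks whose centralities
    are identical by construction).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("vectors must have equal length")
    if a.shape[0] < 2:
        raise ValueError("need at least two values")
    ra, rb = rankdata(a), rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def all_centralities(network) -> dict[str, np.ndarray]:
    """All three metrics for one network, keyed by metric name."""
    in_s, out_s = strength_centralities(network)
    return {"in_strength": in_s, "out_strength": out_s,
            "betweenness": betweenness(network)}


def centrality_table(networks: dict) -> pd.DataFrame:
    """Tidy (pseudo-subject, node, metric, value) table for a set of networks."""
    rows = []
    for pid, net in networks.items():
        cents = all_centralities(net)
        for metric, values in cents.items():
            for j, v in enumerate(values):
                rows.append({"pseudo_subject": pid,
                             "node": net.symptom_names[j],
                             "metric": metric, "value": v})
    return pd.DataFrame(rows)
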