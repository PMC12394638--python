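"""Synthetic panel generators for the simulation study designs.

Ground-truth networks come in two flavors:

* a *stable* truth: a Watts-Strogatz small-world static network drives the
  first timepoint, and the temporal adjacency has 20 nonzero directed
  effects — 15 fixed at weight 1 and 5 moderated by Bernoulli(0.5) binary
  covariates with effect size beta = 2 — so edge positions and strengths are
  heterogeneous across nodes and subjects;
* an *unstable* truth: a covariate-free directed ring in which every node
  has identical in-strength, out-strength, and betweenness by construction,
  so centrality orderings carry no signal.

The first timepoint is drawn from the Ising model implied by the static
adjacency and the thresholds via Gibbs sampling; later timepoints follow the
lag-1 logistic autoregression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model_core import ModelParams, SymptomPanel, inverse_logit

__all__ = [
    "TruthSpec", "watts_strogatz_adjacency", "sample_initial_states",
    "make_temporal_truth", "make_ring_truth", "sample_covariates",
    "simulate_panel",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


@dataclass
class TruthSpec:
    """Ground truth for a simulated panel.

    params : generating ModelParams.
    static_adjacency : (p, p) symmetric 0/1 matrix for the t=1 Ising model.
    edge_mask : (p, p) bool, True where sigma1 is nonzero.
    cov_edge_mask : (p, p, d) bool, True where gamma1 is nonzero.
    meta : generator settings for provenance.
    """

    params: ModelParams
    static_adjacency: np.ndarray
    edge_mask: np.ndarray
    cov_edge_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        A = np.asarray(self.static_adjacency)
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("static adjacency must be symmetric with zero "
                             "diagonal")
        if not np.array_equal(self.edge_mask, self.params.sigma1 != 0):
            raise ValueError("edge_mask inconsistent with sigma1")
        if not np.array_equal(self.cov_edge_mask, self.params.gamma1 != 0):
            raise ValueError("cov_edge_mask inconsistent with gamma1")

    @property
    def n_temporal_effects(self) -> int:
        return int(self.edge_mask.sum() + self.cov_edge_mask.sum())


def watts_strogatz_adjacency(p: int, k: int = 2, theta: float = 0.3,
                             seed=None) -> np.ndarray:
    """Symmetric 0/1 adjacency of a Watts-Strogatz small-world graph.

    Starts from a ring lattice where each node connects to its k nearest
    neighbors (k/2 per side) and rewires each edge independently with
    probability theta, avoiding self-loops and duplicate edges, so the
    undirected edge count is exactly p*k/2.
    """
    if p < 3:
        raise ValueError("need at least 3 nodes")
    if k >= p:
        raise ValueError(f"neighbor count k={k} must be below p={p}")
    if k % 2 or k <= 0:
        raise ValueError("k is a total lattice degree and must be a positive "
                         "even number")
    if not 0 <= theta <= 1:
        raise ValueError("rewiring probability must be in [0, 1]")
    rng = _rng(seed)
    g = nx.watts_strogatz_graph(p, k, theta,
                                seed=int(rng.integers(2 ** 31)))
    return nx.to_numpy_array(g, nodelist=range(p), dtype=np.int64)


def sample_initial_states(static_adjacency, mu, n: int,
                          gibbs_sweeps: int = 200, seed=None) -> np.ndarray:
    """Draw n independent t=1 symptom vectors from the Ising-type model.

    Full conditionals are P(y_j = 1 | rest) = logit^{-1}(mu_j +
    sum_{j'} A[j, j'] y_{j'}); a systematic-scan Gibbs sampler is run for
    `gibbs_sweeps` sweeps per subject, vectorized across subjects.
    """
    A = np.asarray(static_adjacency, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if not np.array_equal(A, A.T):
        raise ValueError("static adjacency must be symmetric")
    if gibbs_sweeps < 1:
        raise ValueError("need at least one Gibbs sweep")
    rng = _rng(seed)
    p = mu.shape[0]
    y = (rng.random((n, p)) < inverse_logit(mu)[None, :]).astype(np.float64)
    for _ in range(gibbs_sweeps):
        for j in range(p):
            eta = mu[j] + y @ A[j]
            y[:, j] = rng.random(n) < inverse_logit(eta)
    return y.astype(np.int8)


def make_temporal_truth(p: int = 10, n_edges: int = 20, n_fixed: int = 15,
                        fixed_weight: float = 1.0, beta: float = 2.0,
                        d: int = 5, mu_value: float = -2.0,
                        theta: float = 0.3, k: int = 2, seed=None) -> TruthSpec:
    """Stable simulation truth: small-world static net, mixed temporal edges.

    Samples `n_edges` ordered (outcome, predictor) pairs uniformly without
    replacement from all p^2 pairs — self-loops (symptom persistence) are
    eligible.  `n_fixed` of them get sigma1 = fixed_weight; each remaining
    pair gets gamma1[j, j', l] = beta for one distinct covariate l, so edge
    strength depends on the subject's covariates.  Thresholds are mu_value
    everywhere and alpha is zero.
    """
    if n_edges > p * p:
        raise ValueError("more edges requested than ordered pairs available")
    if not 0 <= n_fixed <= n_edges:
        raise ValueError("n_fixed must be between 0 and n_edges")
    if n_edges - n_fixed > d:
        raise ValueError("need one distinct covariate per moderated edge")
    rng = _rng(seed)
    ws_seed = int(rng.integers(2 ** 31))
    static = watts_strogatz_adjacency(p, k=k, theta=theta, seed=ws_seed)

    pairs = rng.choice(p * p, size=n_edges, replace=False)
    params = ModelParams.zeros(p, d)
    params.mu[:] = mu_value
    for idx in pairs[:n_fixed]:
        params.sigma1[idx // p, idx % p] = fixed_weight
    mod_covs = rng.choice(d, size=n_edges - n_fixed, replace=False) \
        if n_edges > n_fixed else np.empty(0, dtype=int)
    for idx, l in zip(pairs[n_fixed:], mod_covs):
        params.gamma1[idx // p, idx % p, l] = beta
    meta = {"kind": "stable", "p": p, "n_edges": n_edges, "n_fixed": n_fixed,
            "fixed_weight": fixed_weight, "beta": beta, "d": d,
            "mu_value": mu_value, "theta": theta, "k": k, "seed": seed}
    return TruthSpec(params, static, params.sigma1 != 0, params.gamma1 != 0,
                     meta)


def make_ring_truth(p: int, weight: float = 1.0,
                    mu_value: float = -2.0) -> TruthSpec:
    """Unstable simulation truth: covariate-free directed ring.

    sigma1 carries a single directed cycle 1 -> 2 -> ... -> p -> 1 with the
    given weight, so every node has in-degree and out-degree one and all
    nodes share identical centralities.  The static network is the
    un-rewired ring lattice, preserving the all-nodes-identical symmetry at
    t = 1.  No covariates (d = 0).
    """
    if p < 3:
        raise ValueError("need at least 3 nodes")
    params = ModelParams.zeros(p, 0)
    params.mu[:] = mu_value
    for j in range(p):
        params.sigma1[(j + 1) % p, j] = weight
    static = watts_strogatz_adjacency(p, k=2, theta=0.0, seed=0)
    meta = {"kind": "unstable", "p": p, "weight": weight,
            "mu_value": mu_value}
    return TruthSpec(params, static, params.sigma1 != 0, params.gamma1 != 0,
                     meta)


def sample_covariates(n: int, d: int = 5, prob: float = 0.5,
                      seed=None) -> np.ndarray:
    """i.i.d. Bernoulli(prob) binary covariate matrix of shape (n, d)."""
    if not 0 <= prob <= 1:
        raise ValueError("prob must be in [0, 1]")
    rng = _rng(seed)
    return (rng.random((n, d)) < prob).astype(np.float64)


def simulate_panel(truth: TruthSpec, X, T: int, seed=None,
                   gibbs_sweeps: int = 200) -> SymptomPanel:
    """Simulate a panel: Ising draw at t=1, lag-1 autoregression for t >= 2."""
    if T < 2:
        raise ValueError("need at least two timepoints")
    rng = _rng(seed)
    params = truth.params
    p, d = params.n_symptoms, params.n_covariates
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != d and not (d == 0 and X.size == 0):
        raise ValueError(f"covariate matrix has {X.shape[1]} columns; "
                         f"truth expects {d}")
    n = X.shape[0]
    y = np.empty((n, T, p), dtype=np.int8)
    y[:, 0, :] = sample_initial_states(truth.static_adjacency, params.mu, n,
                                       gibbs_sweeps=gibbs_sweeps, seed=rng)
    thr = params.mu[None, :] + X @ params.alpha.T
    for t in range(1, T):
        y_prev = y[:, t - 1, :].astype(np.float64)
        eta = thr + y_prev @ params.sigma1.T
        if d:
            eta = eta + np.einsum("nl,jkl,nk->nj", X, params.gamma1, y_prev)
        y[:, t, :] = rng.random((n, p)) < inverse_logit(eta)
    return SymptomPanel(y, X)
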