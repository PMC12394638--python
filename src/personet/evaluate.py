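"""Edge-recovery scoring and the three simulation studies.

Edge identification is scored jointly over every sigma1 entry (p^2) and
every gamma1 entry (p^2 * d) against the generating truth masks: an entry
is "called" when its estimate exceeds `tol` in magnitude (0 by default —
eLasso already zeroes negligible effects).  Both the false positive rate
and the false discovery rate are reported alongside TPR and Matthews'
correlation coefficient.

`run_simulation_study` orchestrates three replicated experiments:

* ``edge_identification`` — stable truths, node-wise eLasso fits over a
  grid of sample sizes and eta values, confusion summaries per replicate;
* ``stability`` — stable vs ring (unstable) truths, case-dropping
  bootstrap correlations of centrality orderings;
* ``difference_type1`` — ring truths where every true edge weight and
  every centrality is identical by construction, so each paired bootstrap
  difference test is a draw under the null; the rejection fraction over
  truly-equal pairs estimates the type-I error.

Replicates are independently sub-seeded from a master seed, so results do
not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap_infer import (bootstrap_network_draws, case_dropping_stability,
                              difference_test, make_pseudo_subjects,
                              quantile_type6)
from .centrality import METRICS
from .estimate import fit_paths, select_network
from .model_core import ModelParams
from .simulate import (TruthSpec, make_ring_truth, make_temporal_truth,
                       sample_covariates, simulate_panel)

__all__ = ["EdgeEvalResult", "classify_edges", "rates",
           "run_simulation_study", "summarize_study"]


@dataclass
class EdgeEvalResult:
    """Confusion counts over all sigma1 and gamma1 entries."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_edges(estimate: ModelParams, truth: TruthSpec,
                   tol: float = 0.0) -> EdgeEvalResult:
    """Confusion counts of called vs true temporal effects."""
    t = truth.params
    if estimate.sigma1.shape != t.sigma1.shape \
            or estimate.gamma1.shape != t.gamma1.shape:
        raise ValueError("estimate and truth dimensions differ")
    called = np.concatenate([(np.abs(estimate.sigma1) > tol).ravel(),
                             (np.abs(estimate.gamma1) > tol).ravel()])
    true = np.concatenate([truth.edge_mask.ravel(),
                           truth.cov_edge_mask.ravel()])
    tp = int(np.sum(called & true))
    fp = int(np.sum(called & ~true))
    fn = int(np.sum(~called & true))
    tn = int(np.sum(~called & ~true))
    return EdgeEvalResult(tp, fp, tn, fn)


def rates(counts) -> dict:
    """TPR, FPR, FDR and Matthews correlation from confusion counts.

    Degenerate denominators: FDR is 0 when nothing is called; MCC is 0 when
    any marginal of the confusion table is empty.
    """
    if isinstance(counts, EdgeEvalResult):
        tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    else:
        tp, fp, tn, fn = counts
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    fdr = fp / (fp + tp) if fp + tp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return {"tpr": tpr, "fpr": fpr, "fdr": fdr, "mcc": float(mcc)}


def _spawn(master_seed, *keys):
    """Deterministic per-task substream below 2^31."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF]
                                + [int(k) & 0x7FFFFFFF for k in keys])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# study pipelines

def _study_edge_identification(cfg) -> pd.DataFrame:
    p = cfg.get("p", 10)
    T = cfg.get("T", 3)
    n_grid = cfg.get("n_grid", [200, 500, 800, 1000])
    etas = cfg.get("etas", [0.25, 0.5, 1.0])
    replicates = cfg.get("replicates", 200)
    tol = cfg.get("tol", 0.0)
    seed = cfg.get("seed", 0)
    rows = []
    for ni, n in enumerate(n_grid):
        for r in range(replicates):
            rng = _spawn(seed, 1, ni, r)
            truth = make_temporal_truth(p=p, seed=rng)
            X = sample_covariates(n, d=truth.params.n_covariates, seed=rng)
            panel = simulate_panel(truth, X, T, seed=rng)
            paths = fit_paths(panel)
            for eta in etas:
                fit = select_network(paths, panel, eta)
                res = classify_edges(fit.params, truth, tol=tol)
                row = {"study": "edge_identification", "n": n, "eta": eta,
                       "replicate": r, "tp": res.tp, "fp": res.fp,
                       "tn": res.tn, "fn": res.fn}
                row.update(rates(res))
                rows.append(row)
    return pd.DataFrame(rows)


def _study_stability(cfg) -> pd.DataFrame:
    p = cfg.get("p", 10)
    T = cfg.get("T", 3)
    n_grid = cfg.get("n_grid", [400, 1000, 1600, 2000])
    deltas = cfg.get("deltas", [0.9, 0.8, 0.7, 0.6, 0.5])
    B = cfg.get("bootstraps", 500)
    eta = cfg.get("eta", 0.25)
    replicates = cfg.get("replicates", 200)
    kinds = cfg.get("kinds", ["stable", "unstable"])
    seed = cfg.get("seed", 0)
    rows = []
    for ki, kind in enumerate(kinds):
        for ni, n in enumerate(n_grid):
            for r in range(replicates):
                rng = _spawn(seed, 2, ki, ni, r)
                if kind == "stable":
                    truth = make_temporal_truth(p=p, seed=rng)
                    X = sample_covariates(n, d=truth.params.n_covariates,
                                          seed=rng)
                else:
                    truth = make_ring_truth(p)
                    X = np.empty((n, 0))
                panel = simulate_panel(truth, X, T, seed=rng)
                # data-splitting design: the reference network comes from
                # one half, case-dropping operates on the other, so under
                # equal true centralities the two orderings share no
                # estimation noise
                perm = rng.permutation(n)
                ref_panel = panel.subset(perm[:n // 2])
                drop_panel = panel.subset(perm[n // 2:])
                stab = case_dropping_stability(
                    drop_panel, eta=eta, proportions=deltas, B=B,
                    seed=int(rng.integers(2 ** 31)),
                    reference_panel=ref_panel)
                for (delta, metric), cors in stab.correlations.items():
                    rows.append({"study": "stability", "kind": kind, "n": n,
                                 "eta": eta, "replicate": r,
                                 "proportion_retained": delta,
                                 "metric": metric,
                                 "mean_correlation": float(np.mean(cors))})
    return pd.DataFrame(rows)


def _equal_pairs(k):
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def _split_draws(panel, eta, R, seed, profiles):
    """Split-replicate draws of all parameters and of profile centralities.

    Wraps `split_inference` and derives, for each replicate's parameter
    draw, the centrality metrics of every pseudo-subject's personal
    network, so edge and centrality draws stay paired by replicate.
    """
    from .bootstrap_infer import BootstrapDraws
    from .centrality import all_centralities
    from .estimate import split_inference
    from .model_core import vector_to_params, personal_network

    res = split_inference(panel, eta=eta, R=R, seed=seed)
    labels = [f"{m}[{ps.id}:{s}]" for m in METRICS for ps in profiles
              for s in panel.symptom_names]
    cent = np.empty((R, len(labels)))
    for r in range(R):
        params = vector_to_params(res.draws[r], panel.n_symptoms,
                                  panel.n_covariates)
        per_profile = [all_centralities(personal_network(params, ps.profile))
                       for ps in profiles]
        cent[r] = np.concatenate([c[m] for m in METRICS
                                  for c in per_profile])
    edge = BootstrapDraws(res.draws, res.labels, R)
    cents = BootstrapDraws(cent, labels, R)
    return edge, cents


def _study_difference_type1(cfg) -> pd.DataFrame:
    p = cfg.get("p", 10)
    T = cfg.get("T", 3)
    n_grid = cfg.get("n_grid", [200, 500, 800, 1000])
    etas = cfg.get("etas", [0.25])
    B = cfg.get("bootstraps", 500)
    replicates = cfg.get("replicates", 200)
    alpha = cfg.get("alpha", 0.05)
    draws_mode = cfg.get("draws", "split")
    seed = cfg.get("seed", 0)
    truth = make_ring_truth(p)
    # flat indices of the truly-equal quantities: the p unit-weight edges
    d = truth.params.n_covariates
    sigma_offset = p + p * d  # after the mu and alpha blocks
    edge_pairs_jk = list(zip(*np.nonzero(truth.edge_mask)))
    edge_idx = [sigma_offset + j * p + k for j, k in edge_pairs_jk]
    rows = []
    for ni, n in enumerate(n_grid):
        for ei, eta in enumerate(etas):
            for r in range(replicates):
                rng = _spawn(seed, 3, ni, ei, r)
                X = np.empty((n, 0))
                panel = simulate_panel(truth, X, T, seed=rng)
                profiles = make_pseudo_subjects(panel.X,
                                                panel.covariate_kinds)
                if draws_mode == "refit":
                    # conditional-on-selection bootstrap: the full-panel
                    # eLasso fit fixes the support, each draw refits the
                    # selected model on a subject resample
                    from .bootstrap_infer import bootstrap_refit_draws
                    reference, edge_draws, cent_draws = bootstrap_refit_draws(
                        panel, eta=eta, B=B,
                        seed=int(rng.integers(2 ** 31)), profiles=profiles)
                    called = [idx for idx, (j, k)
                              in zip(edge_idx, edge_pairs_jk)
                              if reference.params.sigma1[j, k] != 0.0]
                elif draws_mode == "split":
                    # empirical distributions from data-splitting inference:
                    # each draw selects on one half and refits unpenalized
                    # on the other, so draws carry both selection and
                    # sampling variability
                    edge_draws, cent_draws = _split_draws(
                        panel, eta, B, int(rng.integers(2 ** 31)), profiles)
                    called = list(edge_idx)
                else:
                    reference = select_network(fit_paths(panel), panel, eta)
                    params, cents = bootstrap_network_draws(
                        panel, eta=eta, B=B,
                        seed=int(rng.integers(2 ** 31)), profiles=profiles)
                    edge_draws, cent_draws = params, cents
                    called = [idx for idx, (j, k)
                              in zip(edge_idx, edge_pairs_jk)
                              if reference.params.sigma1[j, k] != 0.0]
                edge_rej = []
                for a, b in _equal_pairs(len(called)):
                    t = difference_test(edge_draws.draws[:, called[a]],
                                        edge_draws.draws[:, called[b]], alpha)
                    edge_rej.append(t["reject"])
                # centralities: all node pairs within each metric
                cent_rej = []
                for m in METRICS:
                    cols = [cent_draws.labels.index(f"{m}[ps:{s}]")
                            for s in panel.symptom_names]
                    for a, b in _equal_pairs(len(cols)):
                        t = difference_test(cent_draws.draws[:, cols[a]],
                                            cent_draws.draws[:, cols[b]],
                                            alpha)
                        cent_rej.append(t["reject"])
                all_rej = edge_rej + cent_rej
                rows.append({
                    "study": "difference_type1", "n": n, "eta": eta,
                    "replicate": r,
                    "edge_pairs": len(edge_rej),
                    "centrality_pairs": len(cent_rej),
                    "edge_rejection": float(np.mean(edge_rej))
                    if edge_rej else np.nan,
                    "centrality_rejection": float(np.mean(cent_rej))
                    if cent_rej else np.nan,
                    "rejection": float(np.mean(all_rej))
                    if all_rej else np.nan})
    return pd.DataFrame(rows)


_STUDIES = {"edge_identification": _study_edge_identification,
            "stability": _study_stability,
            "difference_type1": _study_difference_type1}


def run_simulation_study(config: dict) -> pd.DataFrame:
    """Run a named replicated simulation study; returns per-replicate rows.

    `config` carries the study name under "study" plus its grids (sample
    sizes, eta values, retention proportions), replicate and bootstrap
    counts, and a master seed.  Each replicate runs on an independent
    sub-seeded stream.
    """
    name = config.get("study")
    if name not in _STUDIES:
        raise ValueError(f"unknown study {name!r}; expected one of "
                         f"{sorted(_STUDIES)}")
    return _STUDIES[name](config)


def summarize_study(results: pd.DataFrame, value_columns=None,
                    group_columns=None) -> pd.DataFrame:
    """Mean and type-6 95% band of each metric across replicates."""
    drop = {"replicate", "study", "tp", "fp", "tn", "fn",
            "edge_pairs", "centrality_pairs"}
    if group_columns is None:
        group_columns = [c for c in ("kind", "n", "eta",
                                     "proportion_retained", "metric")
                         if c in results.columns]
    if value_columns is None:
        value_columns = [c for c in results.columns
                         if c not in drop and c not in group_columns
                         and np.issubdtype(results[c].dtype, np.number)]
    rows = []
    for key, grp in results.groupby(group_columns):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(group_columns, key))
        for col in value_columns:
            vals = grp[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append({**base, "quantity": col,
                         "mean": float(np.mean(vals)),
                         "band_low": quantile_type6(vals, 0.025),
                         "band_high": quantile_type6(vals, 0.975),
                         "replicates": int(vals.size)})
    return pd.DataFrame(rows)
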