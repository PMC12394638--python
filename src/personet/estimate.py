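"""Node-wise eLasso estimation of personal temporal symptom networks.

Each symptom j at time t is regressed on the d covariates, the p lagged
symptom indicators, and all p*d covariate-by-lagged-symptom products via an
L1-penalized logistic regression (intercept unpenalized).  The penalty level
is chosen per node by minimizing the extended BIC

    eBIC(lambda) = -2 loglik + |J| log N + 2 eta |J| log P_model

over a 100-point log-spaced path from the data-derived lambda_max down to
lambda_max * 1e-3, where |J| is the number of nonzero penalized
coefficients, N = n (T - 1) the number of transition observations, and
P_model = d + p + p*d the per-node predictor count.  eta >= 0 is a
user-fixed sparsity hyperparameter (0.25 by default); ties across the path
resolve toward the larger penalty (sparser model).

Selected coefficients are reported penalized, as in the eLasso convention.
Debiased estimates and interval summaries come from `split_inference`,
which repeatedly halves the subjects, selects the support on one half, and
refits unpenalized logistic regressions on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _solver
from .model_core import (ModelParams, SymptomPanel, param_labels,
                         params_to_vector)

__all__ = [
    "PanelDesign", "NodePath", "FitResult", "SplitInferenceResult",
    "build_design", "ebic", "fit_node", "fit_paths", "select_network",
    "fit_network", "split_inference", "pseudo_r2", "coefficient_table",
]

DEFAULT_ETA = 0.25
N_LAMBDA = 100
LAMBDA_RATIO = 1e-3
REFIT_CAP = 15.0  # log-odds cap flagging separation in unpenalized refits


@dataclass
class PanelDesign:
    """Stacked transition rows of a panel, shared by all node regressions.

    One row per (subject, transition t=2..T).  Predictor columns are ordered
    [x_1..x_d, y_1^{t-1}..y_p^{t-1}, then x_l * y_{j'}^{t-1} with j' outer
    and l inner]; the intercept is handled separately by the solver.
    """

    X: np.ndarray            # (N, P_model)
    Y: np.ndarray            # (N, p) transition outcomes
    subject_index: np.ndarray  # (N,) subject of each row
    p: int
    d: int
    column_labels: list[str]
    _grouped: object = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def P_model(self) -> int:
        return self.X.shape[1]

    @property
    def grouped(self):
        if self._grouped is None:
            self._grouped = _solver.prepare_design(self.X)
        return self._grouped

    def rows_for_subjects(self, subjects) -> np.ndarray:
        return np.nonzero(np.isin(self.subject_index, subjects))[0]


def build_design(panel: SymptomPanel) -> PanelDesign:
    """Stack the node-regression design for all transitions of a panel."""
    if panel.n_timepoints < 2:
        raise ValueError("no transitions: panel has T < 2")
    n, T, p = panel.y.shape
    d = panel.n_covariates
    y_prev = panel.y[:, :-1, :].reshape(n * (T - 1), p).astype(np.float64)
    y_next = panel.y[:, 1:, :].reshape(n * (T - 1), p).astype(np.float64)
    X_rows = np.repeat(panel.X, T - 1, axis=0)
    inter = (y_prev[:, :, None] * X_rows[:, None, :]).reshape(n * (T - 1),
                                                              p * d)
    X = np.concatenate([X_rows, y_prev, inter], axis=1)
    labels = list(panel.covariate_names)
    labels += [f"{s}[t-1]" for s in panel.symptom_names]
    labels += [f"{s}[t-1]*{c}" for s in panel.symptom_names
               for c in panel.covariate_names]
    subject_index = np.repeat(np.arange(n), T - 1)
    return PanelDesign(X, y_next, subject_index, p, d, labels)


def ebic(loglik: float, J: int, N: int, P_model: int,
         eta: float = DEFAULT_ETA) -> float:
    """Extended BIC: -2 loglik + J log N + 2 eta J log P_model."""
    if N < 1 or J < 0 or P_model < 1 or eta < 0:
        raise ValueError("invalid eBIC arguments")
    return -2.0 * loglik + J * np.log(N) + 2.0 * eta * J * np.log(P_model)


@dataclass
class NodePath:
    """Full penalty path of one node regression."""

    j: int
    lambdas: np.ndarray      # (L,) decreasing
    coefs: np.ndarray        # (L, P_model) penalized coefficients
    intercepts: np.ndarray   # (L,)
    logliks: np.ndarray      # (L,)
    nnz: np.ndarray          # (L,)
    N: int
    P_model: int
    null_loglik: float

    def ebic_values(self, eta: float) -> np.ndarray:
        return (-2.0 * self.logliks + self.nnz * np.log(self.N)
                + 2.0 * eta * self.nnz * np.log(self.P_model))

    def select(self, eta: float) -> int:
        """Index of the eBIC-minimizing penalty (ties -> larger lambda)."""
        return int(np.argmin(self.ebic_values(eta)))


def _fit_node_path(design: PanelDesign, j: int,
                   lambdas=None) -> NodePath:
    g = design.grouped
    y = design.Y[:, j]
    total = y.sum()
    if total <= 0 or total >= design.N:
        raise ValueError(
            f"outcome for node {j} has a single class; cannot fit")
    suc = g.successes(y)
    if lambdas is None:
        lambdas = _solver.lambda_path(g, suc, n_lambda=N_LAMBDA,
                                      ratio=LAMBDA_RATIO)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if lambdas.size == 0:
        raise ValueError("empty lambda path")
    coefs, intercepts, logliks, nnz = _solver.logistic_lasso_path(
        g, suc, lambdas)
    ybar = total / design.N
    null_ll = design.N * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    return NodePath(j, lambdas, coefs, intercepts, logliks, nnz,
                    design.N, design.P_model, float(null_ll))


def fit_paths(panel: SymptomPanel, design: PanelDesign = None) -> list[NodePath]:
    """Fit all p node penalty paths once; selection can then vary eta."""
    if design is None:
        design = build_design(panel)
    paths = []
    for j in range(design.p):
        try:
            paths.append(_fit_node_path(design, j))
        except ValueError as err:
            raise ValueError(f"node {j} ({panel.symptom_names[j]}): {err}") \
                from err
    return paths


@dataclass
class NodeFit:
    """Selected coefficients of one node regression, mapped to model roles."""

    j: int
    mu: float
    alpha: np.ndarray        # (d,)
    sigma: np.ndarray        # (p,)
    gamma: np.ndarray        # (p, d)
    lambda_selected: float
    J: int
    loglik: float
    ebic: float
    pseudo_r2: float
    path: NodePath


def _select_node(path: NodePath, eta: float, p: int, d: int) -> NodeFit:
    li = path.select(eta)
    coef = path.coefs[li]
    alpha = coef[:d]
    sigma = coef[d:d + p]
    gamma = coef[d + p:].reshape(p, d)
    denom = path.null_loglik
    pr2 = 1.0 - path.logliks[li] / denom if denom != 0 else np.nan
    return NodeFit(path.j, float(path.intercepts[li]), alpha, sigma, gamma,
                   float(path.lambdas[li]), int(path.nnz[li]),
                   float(path.logliks[li]),
                   float(path.ebic_values(eta)[li]), float(pr2), path)


@dataclass
class FitResult:
    """Assembled network estimate with per-node selection traces."""

    params: ModelParams
    eta: float
    per_node: list[NodeFit]
    N: int
    P_model: int
    symptom_names: list[str]
    covariate_names: list[str]

    @property
    def loglik(self) -> float:
        return float(sum(nf.loglik for nf in self.per_node))


def fit_node(j: int, panel: SymptomPanel, eta: float = DEFAULT_ETA,
             lambda_path=None) -> NodeFit:
    """eLasso fit of a single node regression at the given eta."""
    design = build_design(panel)
    if not 0 <= j < design.p:
        raise IndexError(f"symptom index {j} out of range for p={design.p}")
    try:
        path = _fit_node_path(design, j, lambdas=lambda_path)
    except ValueError as err:
        raise ValueError(f"node {j} ({panel.symptom_names[j]}): {err}") \
            from err
    return _select_node(path, eta, design.p, design.d)


def select_network(paths: list[NodePath], panel: SymptomPanel,
                   eta: float = DEFAULT_ETA) -> FitResult:
    """Assemble a FitResult from pre-fitted node paths at the given eta."""
    p, d = panel.n_symptoms, panel.n_covariates
    params = ModelParams.zeros(p, d)
    fits = []
    for path in paths:
        nf = _select_node(path, eta, p, d)
        params.mu[nf.j] = nf.mu
        params.alpha[nf.j] = nf.alpha
        params.sigma1[nf.j] = nf.sigma
        params.gamma1[nf.j] = nf.gamma
        fits.append(nf)
    return FitResult(params, eta, fits, paths[0].N, paths[0].P_model,
                     list(panel.symptom_names), list(panel.covariate_names))


def fit_network(panel: SymptomPanel, eta: float = DEFAULT_ETA) -> FitResult:
    """Fit the personal temporal network by p node-wise eLasso regressions."""
    design = build_design(panel)
    return select_network(fit_paths(panel, design), panel, eta)


def pseudo_r2(node_fit: NodeFit, panel: SymptomPanel) -> float:
    """McFadden pseudo-R^2 of a node fit: 1 - loglik / loglik_intercept."""
    design = build_design(panel)
    j = node_fit.j
    coef = np.concatenate([node_fit.alpha, node_fit.sigma,
                           node_fit.gamma.ravel()])
    g = design.grouped
    suc = g.successes(design.Y[:, j])
    ll = _solver.grouped_loglik(g, suc, coef, node_fit.mu)
    ybar = design.Y[:, j].mean()
    if ybar <= 0 or ybar >= 1:
        raise ValueError("intercept-only likelihood is degenerate")
    ll0 = design.N * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    return 1.0 - ll / ll0


# ---------------------------------------------------------------------------
# data-splitting inference

@dataclass
class SplitInferenceResult:
    """Aggregated half-splitting refit draws for every model parameter.

    draws[r, k] is replicate r's estimate of parameter k in the
    params_to_vector layout; parameters unselected in a replicate
    contribute 0.  CIs are 95% type-6 quantiles over replicates.
    """

    draws: np.ndarray            # (R, K)
    mean_estimate: np.ndarray    # (K,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    selection_frequency: np.ndarray
    R: int
    labels: list[str]
    p: int
    d: int
    n_capped: int = 0

    @property
    def params_mean(self) -> ModelParams:
        from .model_core import vector_to_params
        return vector_to_params(self.mean_estimate, self.p, self.d)


def split_inference(panel: SymptomPanel, eta: float = DEFAULT_ETA,
                    R: int = 100, seed=None) -> SplitInferenceResult:
    """Data-splitting inference: select on half A, refit unpenalized on B.

    For each of R replicates the subjects are randomly halved; eLasso on
    half A picks each node's support, and an unpenalized logistic regression
    of the same node on half B, restricted to the selected predictors plus
    intercept, provides the replicate's estimates.  Unselected parameters
    enter the replicate draw as 0.  Refit coefficients are capped at
    +/-15 log-odds (separation guard); capped replicates are counted.
    """
    from .bootstrap_infer import quantile_type6

    n = panel.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    rng = np.random.default_rng(seed)
    p, d = panel.n_symptoms, panel.n_covariates
    design_full = build_design(panel)
    K = p + p * d + p * p + p * p * d
    draws = np.zeros((R, K))
    selected = np.zeros((R, K), dtype=bool)
    n_capped = 0

    # index helpers from node-regression columns to the flat vector
    def flat_indices(j):
        idx = np.empty(d + p + p * d, dtype=np.int64)
        idx[:d] = p + j * d + np.arange(d)                       # alpha[j, :]
        idx[d:d + p] = p + p * d + j * p + np.arange(p)          # sigma1[j, :]
        idx[d + p:] = p + p * d + p * p + j * p * d + np.arange(p * d)
        return idx

    node_flat = [flat_indices(j) for j in range(p)]
    mu_flat = np.arange(p)

    for r in range(R):
        perm = rng.permutation(n)
        half_a, half_b = perm[:n // 2], perm[n // 2:]
        fit_a = fit_network(panel.subset(half_a), eta)
        rows_b = design_full.rows_for_subjects(half_b)
        X_b = design_full.X[rows_b]
        capped_rep = False
        for j in range(p):
            coef_a = np.concatenate([fit_a.per_node[j].alpha,
                                     fit_a.per_node[j].sigma,
                                     fit_a.per_node[j].gamma.ravel()])
            support = np.nonzero(coef_a)[0]
            y_b = design_full.Y[rows_b, j]
            selected[r, node_flat[j][support]] = True
            selected[r, mu_flat[j]] = True
            Xs = X_b[:, support]
            Xu, inv, cnt = np.unique(Xs, axis=0, return_inverse=True,
                                     return_counts=True)
            suc = np.bincount(inv, weights=y_b, minlength=Xu.shape[0])
            if suc.sum() <= 0 or suc.sum() >= y_b.size:
                # no information in this half; treat node as unselected
                capped_rep = True
                continue
            beta, b0, capped = _solver.logistic_refit(
                Xu, cnt.astype(np.float64), suc, cap=REFIT_CAP)
            capped_rep = capped_rep or capped
            draws[r, mu_flat[j]] = b0
            draws[r, node_flat[j][support]] = beta
        if capped_rep:
            n_capped += 1

    mean_est = draws.mean(axis=0)
    ci_low = np.array([quantile_type6(draws[:, k], 0.025) for k in range(K)])
    ci_high = np.array([quantile_type6(draws[:, k], 0.975) for k in range(K)])
    sel_freq = selected.mean(axis=0)
    labels = param_labels(panel.symptom_names, panel.covariate_names)
    return SplitInferenceResult(draws, mean_est, ci_low, ci_high, sel_freq,
                                R, labels, p, d, n_capped)


def coefficient_table(result, panel: SymptomPanel):
    """Flat coefficient table (one row per parameter) for export.

    Accepts a FitResult (estimate column only) or a SplitInferenceResult
    (estimate, CI bounds, selection frequency).
    """
    import pandas as pd

    p, d = panel.n_symptoms, panel.n_covariates
    labels = param_labels(panel.symptom_names, panel.covariate_names)
    roles = (["mu"] * p + ["alpha"] * (p * d) + ["sigma1"] * (p * p)
             + ["gamma1"] * (p * p * d))
    if isinstance(result, SplitInferenceResult):
        df = pd.DataFrame({"parameter": labels, "role": roles,
                           "estimate": result.mean_estimate,
                           "ci_low": result.ci_low,
                           "ci_high": result.ci_high,
                           "selection_frequency": result.selection_frequency})
    else:
        df = pd.DataFrame({"parameter": labels, "role": roles,
                           "estimate": params_to_vector(result.params)})
    return df
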