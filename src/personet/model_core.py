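"""Covariate-moderated lag-1 logistic autoregression for binary symptom panels.

The model: for subject i with covariate profile x and symptom vector
y^{t-1} at the previous timepoint, the probability that symptom j is
present at time t is

    P(y_j^t = 1 | y^{t-1}, x)
        = logit^{-1}( tau_j(x) + sum_{j'} W(x)[j, j'] * y_{j'}^{t-1} )

with personal thresholds and edge weights

    tau_j(x)     = mu_j + sum_l alpha[j, l] * x_l
    W(x)[j, j']  = sigma1[j, j'] + sum_l gamma1[j, j', l] * x_l .

``sigma1`` rows index the time-t outcome and columns the (t-1) predictor:
W[j, j'] is the directed edge j' -> j.  The lag is fixed at one; every
quantity in this package (likelihoods, fits, networks) uses this
parameterization.  W(x) realized for a single covariate profile is the
*personal temporal symptom network* of that profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SymptomPanel", "ModelParams", "PersonalNetwork",
    "inverse_logit", "node_probability", "log_likelihood", "personal_network",
    "params_to_vector", "vector_to_params", "param_labels",
]

_KINDS = ("binary", "numeric")


@dataclass
class SymptomPanel:
    """Longitudinal binary symptom observations with subject covariates.

    Attributes
    ----------
    y : (n, T, p) array of 0/1 symptom indicators.
    X : (n, d) covariate matrix; binary columns contain only {0, 1}.
    symptom_names : p labels.
    covariate_names : d labels.
    covariate_kinds : d flags, each "binary" or "numeric".
    """

    y: np.ndarray
    X: np.ndarray
    symptom_names: list[str] = field(default=None)
    covariate_names: list[str] = field(default=None)
    covariate_kinds: list[str] = field(default=None)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.ndim != 3:
            raise ValueError("y must be (subjects, timepoints, symptoms)")
        n, T, p = self.y.shape
        if T < 2:
            raise ValueError("panel needs T >= 2 timepoints")
        if p < 2:
            raise ValueError("panel needs p >= 2 symptoms")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("symptom indicators must be 0 or 1")
        self.y = self.y.astype(np.int8)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.size == 0:
            self.X = self.X.reshape(n, 0)
        if self.X.shape[0] != n:
            raise ValueError(
                f"covariate rows ({self.X.shape[0]}) != subjects ({n})")
        d = self.X.shape[1]
        if self.symptom_names is None:
            self.symptom_names = [f"Y{j + 1}" for j in range(p)]
        if self.covariate_names is None:
            self.covariate_names = [f"X{l + 1}" for l in range(d)]
        if self.covariate_kinds is None:
            self.covariate_kinds = [
                "binary" if np.isin(self.X[:, l], (0, 1)).all() else "numeric"
                for l in range(d)]
        if len(self.symptom_names) != p or len(self.covariate_names) != d \
                or len(self.covariate_kinds) != d:
            raise ValueError("label lengths do not match panel dimensions")
        for l, kind in enumerate(self.covariate_kinds):
            if kind not in _KINDS:
                raise ValueError(f"unknown covariate kind {kind!r}")
            col = self.X[:, l]
            if kind == "binary" and not np.isin(col, (0, 1)).all():
                raise ValueError(
                    f"binary covariate {self.covariate_names[l]!r} has "
                    "values outside {0, 1}")
            if not np.isfinite(col).all():
                raise ValueError(
                    f"covariate {self.covariate_names[l]!r} has non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.y.shape[1]

    @property
    def n_symptoms(self) -> int:
        return self.y.shape[2]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SymptomPanel":
        """Panel restricted to the given subject indices (allows repeats)."""
        idx = np.asarray(idx)
        return SymptomPanel(self.y[idx], self.X[idx], self.symptom_names,
                            self.covariate_names, list(self.covariate_kinds))


@dataclass
class ModelParams:
    """Parameters of the covariate-moderated lag-1 model.

    mu : (p,) thresholds, log-odds of presence with all lagged symptoms
        absent and x = 0.
    alpha : (p, d) covariate effects on the thresholds.
    sigma1 : (p, p) lag-1 edge matrix; [j, j'] is the effect of symptom j'
        at t-1 on symptom j at t (row = outcome).
    gamma1 : (p, p, d) covariate effects moderating sigma1.
    """

    mu: np.ndarray
    alpha: np.ndarray
    sigma1: np.ndarray
    gamma1: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.sigma1 = np.asarray(self.sigma1, dtype=np.float64)
        self.gamma1 = np.asarray(self.gamma1, dtype=np.float64)
        p = self.mu.shape[0]
        if self.alpha.ndim != 2 or self.alpha.shape[0] != p:
            raise ValueError("alpha must be (p, d)")
        d = self.alpha.shape[1]
        if self.sigma1.shape != (p, p):
            raise ValueError("sigma1 must be (p, p)")
        if self.gamma1.shape != (p, p, d):
            raise ValueError("gamma1 must be (p, p, d)")
        for name in ("mu", "alpha", "sigma1", "gamma1"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} has non-finite entries")

    @property
    def n_symptoms(self) -> int:
        return self.mu.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.alpha.shape[1]

    @classmethod
    def zeros(cls, p: int, d: int) -> "ModelParams":
        return cls(np.zeros(p), np.zeros((p, d)), np.zeros((p, p)),
                   np.zeros((p, p, d)))


@dataclass
class PersonalNetwork:
    """The directed weighted temporal network realized for one profile x.

    weights[j, j'] = sigma1[j, j'] + sum_l gamma1[j, j', l] * x_l is the
    directed edge j' -> j; thresholds[j] = mu_j + sum_l alpha[j, l] * x_l.
    """

    weights: np.ndarray
    thresholds: np.ndarray
    profile: np.ndarray
    symptom_names: list[str] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if not (np.isfinite(self.weights).all()
                and np.isfinite(self.thresholds).all()):
            raise ValueError("network weights and thresholds must be finite")
        if self.symptom_names is None:
            self.symptom_names = [f"Y{j + 1}" for j in
                                  range(self.thresholds.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.thresholds.shape[0]


def inverse_logit(z):
    """Numerically stable logistic function exp(z) / (1 + exp(z)).

    Total on the extended reals: -inf -> 0, +inf -> 1, no overflow for
    large |z|.
    """
    return expit(z)


def personal_network(params: ModelParams, x) -> PersonalNetwork:
    """Realize the personal network W(x), tau(x) for covariate profile x."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != params.n_covariates:
        raise ValueError(
            f"profile length {x.shape[0]} != number of covariates "
            f"{params.n_covariates}")
    weights = params.sigma1 + params.gamma1 @ x if x.size else params.sigma1.copy()
    thresholds = params.mu + params.alpha @ x if x.size else params.mu.copy()
    return PersonalNetwork(weights, thresholds, x)


def node_probability(params: ModelParams, x, y_prev, j: int) -> float:
    """P(y_j^t = 1 | y^{t-1} = y_prev, covariates x) under the model."""
    p = params.n_symptoms
    if not -p <= j < p:
        raise IndexError(f"symptom index {j} out of range for p={p}")
    net = personal_network(params, x)
    y_prev = np.asarray(y_prev, dtype=np.float64).ravel()
    if y_prev.shape[0] != p:
        raise ValueError("y_prev length does not match number of symptoms")
    return float(inverse_logit(net.thresholds[j] + net.weights[j] @ y_prev))


def _linear_predictors(params: ModelParams, panel: SymptomPanel) -> np.ndarray:
    """(n, T-1, p) array of log-odds for each transition outcome."""
    X, y = panel.X, panel.y
    thr = params.mu[None, :] + X @ params.alpha.T          # (n, p)
    y_prev = y[:, :-1, :].astype(np.float64)               # (n, T-1, p)
    base = np.einsum("jk,ntk->ntj", params.sigma1, y_prev)
    if params.n_covariates:
        # covariate-moderated part: sum_l x_il * gamma1[j, j', l] * y_prev
        mod = np.einsum("nl,jkl,ntk->ntj", X, params.gamma1, y_prev)
        base = base + mod
    return base + thr[:, None, :]


def log_likelihood(params: ModelParams, panel: SymptomPanel) -> float:
    """Total Bernoulli log-likelihood over all transitions t = 2..T.

    Decomposes exactly into the sum of the p node-wise conditional
    log-likelihoods, which is what makes node-wise fitting valid.
    """
    if panel.n_timepoints < 2:
        raise ValueError("no transitions: panel has T < 2")
    if params.n_symptoms != panel.n_symptoms:
        raise ValueError("parameter and panel symptom counts differ")
    eta = _linear_predictors(params, panel)
    y_next = panel.y[:, 1:, :]
    return float(np.sum(y_next * eta - np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# flat parameter vector <-> ModelParams, used by bootstrap and split draws

def params_to_vector(params: ModelParams) -> np.ndarray:
    """Flatten to [mu, alpha, sigma1, gamma1] in C order."""
    return np.concatenate([params.mu.ravel(), params.alpha.ravel(),
                           params.sigma1.ravel(), params.gamma1.ravel()])


def vector_to_params(vec, p: int, d: int) -> ModelParams:
    vec = np.asarray(vec, dtype=np.float64)
    sizes = [p, p * d, p * p, p * p * d]
    if vec.shape[0] != sum(sizes):
        raise ValueError("vector length does not match (p, d)")
    parts = np.split(vec, np.cumsum(sizes)[:-1])
    return ModelParams(parts[0], parts[1].reshape(p, d),
                       parts[2].reshape(p, p), parts[3].reshape(p, p, d))


def param_labels(symptom_names, covariate_names) -> list[str]:
    """Labels aligned with params_to_vector: role[outcome,predictor,covariate]."""
    sy, cv = list(symptom_names), list(covariate_names)
    labels = [f"mu[{j}]" for j in sy]
    labels += [f"alpha[{j},{l}]" for j in sy for l in cv]
    labels += [f"sigma1[{j},{k}]" for j in sy for k in sy]
    labels += [f"gamma1[{j},{k},{l}]" for j in sy for k in sy for l in cv]
    return labels
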