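"""Bootstrap accuracy, stability, and difference testing for fitted networks.

Three-step machinery:

1. *Accuracy*: subject-level nonparametric bootstrap of every model
   parameter; 95% CIs are type-6 quantile intervals of the bootstrap draws.
2. *Stability*: case-dropping bootstrap — refit on random subject subsets,
   recompute centralities for a set of representative pseudo-subjects, and
   correlate (Spearman) the subset centrality ordering with the full-sample
   one.  High correlation under heavy dropping indicates interpretable
   centralities.
3. *Difference tests*: paired bootstrap draws of two quantities; the
   difference is declared significant when zero falls outside the type-6
   bootstrap CI of the paired differences.

Pseudo-subjects summarize the covariate population: numeric covariates sit
at their sample means while binary covariates run over all 2^b
combinations, so personal networks need only be realized for those
profiles rather than for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import METRICS, all_centralities, spearman_correlation
from .model_core import SymptomPanel, param_labels, params_to_vector, personal_network

__all__ = [
    "BootstrapDraws", "PseudoSubject", "StabilityResult",
    "quantile_type6", "bootstrap_edges", "bootstrap_network_draws",
    "make_pseudo_subjects", "case_dropping_stability", "difference_test",
]

MAX_BINARY_COVARIATES = 12


def quantile_type6(values, prob: float) -> float:
    """Type-6 sample quantile (plotting position h = (m + 1) * prob).

    With sorted values v_(1..m), returns the linear interpolation between
    v_(floor(h)) and v_(floor(h)+1), clamped to the extremes when h falls
    outside [1, m].
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    m = v.shape[0]
    if m == 0:
        raise ValueError("empty sample")
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    h = (m + 1) * prob
    if h <= 1.0:
        return float(v[0])
    if h >= m:
        return float(v[-1])
    lo = int(np.floor(h))
    return float(v[lo - 1] + (h - lo) * (v[lo] - v[lo - 1]))


@dataclass
class BootstrapDraws:
    """B bootstrap draws for a set of labeled scalar quantities."""

    draws: np.ndarray            # (B, K)
    labels: list[str]
    B: int
    alpha_level: float = 0.05
    n_skipped: int = 0

    def __post_init__(self):
        if self.draws.shape != (self.B, len(self.labels)):
            raise ValueError("draws must be (B, n_labels)")

    def __getitem__(self, label) -> np.ndarray:
        return self.draws[:, self.labels.index(label)]

    def ci(self):
        """(low, high) type-6 interval per quantity at the nominal level."""
        a = self.alpha_level
        low = np.array([quantile_type6(col, a / 2) for col in self.draws.T])
        high = np.array([quantile_type6(col, 1 - a / 2)
                         for col in self.draws.T])
        return low, high


@dataclass
class PseudoSubject:
    """A representative covariate profile for personal-network summaries."""

    profile: np.ndarray
    id: str

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=np.float64)


def make_pseudo_subjects(X, covariate_kinds) -> list[PseudoSubject]:
    """All 2^b binary combinations crossed with numeric covariates at means.

    Ordering is deterministic: binary covariates count up as a big-endian
    counter in covariate order (the first binary covariate is the most
    significant bit).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    kinds = list(covariate_kinds)
    d = X.shape[1] if X.size else len(kinds)
    if len(kinds) != d:
        raise ValueError("covariate_kinds length must match covariate count")
    binary_pos = [l for l, kind in enumerate(kinds) if kind == "binary"]
    b = len(binary_pos)
    if b > MAX_BINARY_COVARIATES:
        raise ValueError(
            f"{b} binary covariates would enumerate {2 ** b} pseudo-subjects;"
            " pass an explicit list of profiles instead")
    base = np.zeros(d)
    for l, kind in enumerate(kinds):
        if kind == "numeric":
            base[l] = X[:, l].mean()
    subjects = []
    for code in range(2 ** b if b else 1):
        profile = base.copy()
        for rank, l in enumerate(binary_pos):
            profile[l] = (code >> (b - 1 - rank)) & 1
        bits = "".join(str(int(profile[l])) for l in binary_pos)
        subjects.append(PseudoSubject(profile, f"ps{bits}" if b else "ps"))
    return subjects


def _resample_fit(panel, eta, rng, estimator, max_tries):
    """One subject-level bootstrap refit; redraws single-class resamples.

    Returns (fit, n_failures): the number of resamples that had to be
    discarded and redrawn before a fittable one appeared.
    """
    n = panel.n_subjects
    for attempt in range(max_tries):
        idx = rng.integers(0, n, size=n)
        try:
            return estimator(panel.subset(idx), eta), attempt
        except ValueError:
            continue
    raise RuntimeError("could not obtain a two-class bootstrap resample")


def bootstrap_network_draws(panel: SymptomPanel, eta: float = 0.25,
                            B: int = 500, seed=None, profiles=None,
                            metrics=METRICS, estimator=None):
    """Subject-level bootstrap of parameters and, optionally, centralities.

    Resamples subjects with replacement, refits the network estimator on
    each resample, and collects every parameter estimate; when `profiles`
    is given, also collects each centrality metric of every pseudo-subject's
    personal network from the same refits.  A resample leaving some node
    with a single-class outcome is redrawn (up to three attempts per draw)
    and counted in ``n_skipped``.

    Returns (param_draws, centrality_draws); the latter is None without
    profiles.  Centrality labels are "metric[pseudo-subject:node]".
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap draws")
    if estimator is None:
        from .estimate import fit_network
        estimator = fit_network
    rng = np.random.default_rng(seed)
    p, d = panel.n_symptoms, panel.n_covariates
    K = p + p * d + p * p + p * p * d
    param_draws = np.empty((B, K))
    n_skipped = 0
    cent_draws = None
    cent_labels = None
    if profiles is not None:
        cent_labels = [f"{m}[{ps.id}:{s}]" for m in metrics for ps in profiles
                       for s in panel.symptom_names]
        cent_draws = np.empty((B, len(cent_labels)))
    for bi in range(B):
        fit, failures = _resample_fit(panel, eta, rng, estimator, max_tries=3)
        n_skipped += failures
        param_draws[bi] = params_to_vector(fit.params)
        if profiles is not None:
            per_profile = [all_centralities(
                personal_network(fit.params, ps.profile)) for ps in profiles]
            cent_draws[bi] = np.concatenate(
                [c[m] for m in metrics for c in per_profile])
    labels = param_labels(panel.symptom_names, panel.covariate_names)
    params = BootstrapDraws(param_draws, labels, B, n_skipped=n_skipped)
    cents = BootstrapDraws(cent_draws, cent_labels, B,
                           n_skipped=n_skipped) if profiles is not None else None
    return params, cents


def bootstrap_edges(panel: SymptomPanel, eta: float = 0.25, B: int = 500,
                    seed=None, estimator=None) -> BootstrapDraws:
    """Subject-level bootstrap draws of every model parameter (Step 1)."""
    params, _ = bootstrap_network_draws(panel, eta, B, seed,
                                        estimator=estimator)
    return params


def bootstrap_refit_draws(panel: SymptomPanel, eta: float = 0.25,
                          B: int = 500, seed=None, profiles=None,
                          metrics=METRICS, fit=None):
    """Conditional-on-selection bootstrap: fixed support, refitted weights.

    The eLasso fit on the full panel fixes each node's selected support;
    each bootstrap draw resamples subjects with replacement and refits the
    *unpenalized* logistic regression of every node on its selected
    predictors.  Draws therefore carry the sampling variability of the
    selected model's coefficients without re-selection noise, which makes
    the CI-based difference tests approximately calibrated when the
    support is stable (re-selection bootstrap draws are overdispersed for
    selected quantities and markedly conservative).

    Returns (fit, param_draws, centrality_draws); centrality_draws is None
    without profiles.
    """
    from . import _solver
    from .estimate import build_design, fit_network
    from .model_core import vector_to_params

    if B < 2:
        raise ValueError("need at least 2 bootstrap draws")
    rng = np.random.default_rng(seed)
    if fit is None:
        fit = fit_network(panel, eta)
    design = build_design(panel)
    n = panel.n_subjects
    p, d = design.p, design.d
    Tm1 = panel.n_timepoints - 1
    K = p + p * d + p * p + p * p * d

    def flat_indices(j):
        idx = np.empty(d + p + p * d, dtype=np.int64)
        idx[:d] = p + j * d + np.arange(d)
        idx[d:d + p] = p + p * d + j * p + np.arange(p)
        idx[d + p:] = p + p * d + p * p + j * p * d + np.arange(p * d)
        return idx

    node_flat = [flat_indices(j) for j in range(p)]
    supports = [np.nonzero(np.concatenate(
        [nf.alpha, nf.sigma, nf.gamma.ravel()]))[0] for nf in fit.per_node]

    param_draws = np.zeros((B, K))
    cent_labels = None
    cent_draws = None
    if profiles is not None:
        cent_labels = [f"{m}[{ps.id}:{s}]" for m in metrics for ps in profiles
                       for s in panel.symptom_names]
        cent_draws = np.empty((B, len(cent_labels)))
    n_skipped = 0
    bi = 0
    while bi < B:
        subj = rng.integers(0, n, size=n)
        rows = (subj[:, None] * Tm1 + np.arange(Tm1)[None, :]).ravel()
        draw = np.zeros(K)
        ok = True
        for j in range(p):
            y = design.Y[rows, j]
            s = y.sum()
            if s <= 0 or s >= y.size:
                ok = False
                break
            Xs = design.X[np.ix_(rows, supports[j])]
            Xu, inv, cnt = np.unique(Xs, axis=0, return_inverse=True,
                                     return_counts=True)
            suc = np.bincount(inv, weights=y, minlength=Xu.shape[0])
            beta, b0, _ = _solver.logistic_refit(Xu, cnt.astype(np.float64),
                                                 suc)
            draw[j] = b0
            draw[node_flat[j][supports[j]]] = beta
        if not ok:
            n_skipped += 1
            if n_skipped > 3 * B:
                raise RuntimeError("too many single-class resamples")
            continue
        param_draws[bi] = draw
        if profiles is not None:
            params_b = vector_to_params(draw, p, d)
            per_profile = [all_centralities(
                personal_network(params_b, ps.profile)) for ps in profiles]
            cent_draws[bi] = np.concatenate(
                [c[m] for m in metrics for c in per_profile])
        bi += 1
    labels = param_labels(panel.symptom_names, panel.covariate_names)
    params = BootstrapDraws(param_draws, labels, B, n_skipped=n_skipped)
    cents = BootstrapDraws(cent_draws, cent_labels, B, n_skipped=n_skipped) \
        if profiles is not None else None
    return fit, params, cents


@dataclass
class StabilityResult:
    """Case-dropping bootstrap correlations per (drop proportion, metric)."""

    correlations: dict = field(default_factory=dict)  # (delta, metric) -> (B,)
    n_skipped: dict = field(default_factory=dict)     # delta -> count
    reference_constant: bool = False

    def mean(self, delta: float, metric: str) -> float:
        return float(np.mean(self.correlations[(delta, metric)]))

    def summary(self) -> pd.DataFrame:
        rows = [{"proportion_retained": dl, "metric": m,
                 "mean_correlation": float(np.mean(c)),
                 "n_bootstraps": len(c)}
                for (dl, m), c in self.correlations.items()]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (dl, m), c in self.correlations.items():
            for bi, v in enumerate(c):
                rows.append({"proportion_retained": dl, "metric": m,
                             "bootstrap": bi, "correlation": v})
        return pd.DataFrame(rows)


def case_dropping_stability(panel: SymptomPanel, eta: float = 0.25,
                            proportions=(0.9, 0.8, 0.7, 0.6, 0.5),
                            B: int = 500, metrics=METRICS, seed=None,
                            estimator=None, profiles=None,
                            min_subjects: int = 50,
                            reference_panel: SymptomPanel = None
                            ) -> StabilityResult:
    """Case-dropping bootstrap of centrality stability (Step 2).

    Fits the reference network (on `reference_panel` when given, otherwise
    on `panel` itself); for each retention proportion and bootstrap,
    refits on ceil(prop * n) subjects of `panel` drawn without
    replacement, computes each metric for every pseudo-subject profile,
    and records the Spearman correlation between the reference and subset
    centrality vectors (concatenated over pseudo-subjects and nodes, one
    correlation per metric per bootstrap).

    Passing a disjoint `reference_panel` (the data-splitting design: one
    half estimates the reference, the other is case-dropped) makes the
    reference and subset orderings independent under the null of equal
    centralities, so unstable networks show near-zero correlations rather
    than the shared-noise correlation that overlapping subsets induce.
    """
    if estimator is None:
        from .estimate import fit_network
        estimator = fit_network
    rng = np.random.default_rng(seed)
    n = panel.n_subjects
    if profiles is None:
        profiles = make_pseudo_subjects(panel.X, panel.covariate_kinds)

    def centrality_vectors(params):
        vecs = {m: [] for m in metrics}
        for ps in profiles:
            net = personal_network(params, ps.profile)
            cents = all_centralities(net)
            for m in metrics:
                vecs[m].append(cents[m])
        return {m: np.concatenate(v) for m, v in vecs.items()}

    ref_fit = estimator(reference_panel if reference_panel is not None
                        else panel, eta)
    reference = centrality_vectors(ref_fit.params)
    ref_constant = any(np.ptp(v) == 0 for v in reference.values())

    result = StabilityResult(reference_constant=ref_constant)
    for prop in proportions:
        keep = int(np.ceil(prop * n))
        if keep < min_subjects:
            raise ValueError(
                f"retaining {keep} subjects at proportion {prop} is below "
                f"the minimum of {min_subjects}")
        cors = {m: [] for m in metrics}
        skipped = 0
        for _ in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                fit = estimator(panel.subset(idx), eta)
            except ValueError:
                skipped += 1
                continue
            sub = centrality_vectors(fit.params)
            for m in metrics:
                cors[m].append(spearman_correlation(reference[m], sub[m]))
        for m in metrics:
            result.correlations[(prop, m)] = np.asarray(cors[m])
        result.n_skipped[prop] = skipped
    return result


def difference_test(draws_a, draws_b, alpha: float = 0.05) -> dict:
    """Paired bootstrap difference test (Step 3).

    Draws must be paired by bootstrap replicate (same resample underlying
    both quantities).  Returns the type-6 CI of the differences and whether
    zero falls outside it.
    """
    a = np.asarray(draws_a, dtype=np.float64).ravel()
    b = np.asarray(draws_b, dtype=np.float64).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("draw vectors must have equal length")
    diff = a - b
    lo = quantile_type6(diff, alpha / 2)
    hi = quantile_type6(diff, 1 - alpha / 2)
    return {"ci_low": lo, "ci_high": hi, "reject": bool(lo > 0 or hi < 0)}
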