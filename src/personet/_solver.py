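"""L1-penalized logistic regression path solver.

Node-wise eLasso fits dominate the cost of every bootstrap and simulation
routine in this package, so the path solver is a compiled routine rather
than a generic GLM fitter, and it exploits the structure of the designs it
sees:

* rows are (covariate, lagged-symptom) indicator patterns, so a panel of
  thousands of transitions collapses to a few hundred distinct rows, shared
  by all p node regressions;
* columns are mostly zero (lagged indicators and their covariate products),
  so gradients are accumulated over stored nonzeros only;
* the Bernoulli log-likelihood Hessian is globally dominated by X'X/4, so a
  single unweighted Gram matrix per design serves every node, every penalty
  level, and every iteration.

The optimizer minimizes the average negative log-likelihood plus an L1
penalty by majorize-minimize: cyclic coordinate descent with
soft-thresholding on the fixed quarter-bound quadratic majorizer, warm
started along a decreasing penalty path.  The intercept is carried as an
unpenalized coordinate.  Predictors are used on their natural scale (no
standardization): designs are 0/1 indicators or products of indicators with
an already-standardized numeric covariate, so coefficients stay
interpretable as log-odds.

scikit-learn's LogisticRegression solves the same problem and serves in the
test suite as an independent cross-check of this solver at fixed penalty.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["GroupedDesign", "prepare_design", "lambda_path", "logistic_lasso_path",
           "logistic_refit", "grouped_loglik"]


class GroupedDesign:
    """A design matrix collapsed to unique rows, with precomputed stencils.

    Attributes
    ----------
    Xu : (R, P) unique design rows.
    cnt : (R,) multiplicities.
    inverse : (N,) index of each original row in Xu; per-node success counts
        are ``np.bincount(inverse, weights=y_j, minlength=R)``.
    G : (P+1, P+1) unweighted Gram of [Xu * sqrt(cnt), 1-column].
    indptr, rowidx, vals : CSC storage of Xu's nonzeros.
    """

    __slots__ = ("Xu", "cnt", "inverse", "G", "indptr", "rowidx", "vals", "N", "P")

    def __init__(self, Xu, cnt, inverse):
        self.Xu = Xu
        self.cnt = cnt
        self.inverse = inverse
        self.N = float(cnt.sum())
        R, P = Xu.shape
        self.P = P
        Xw = Xu * np.sqrt(cnt)[:, None]
        G = np.empty((P + 1, P + 1))
        G[:P, :P] = Xw.T @ Xw
        csum = Xu.T @ cnt
        G[:P, P] = csum
        G[P, :P] = csum
        G[P, P] = self.N
        self.G = G
        indptr = np.zeros(P + 1, dtype=np.int64)
        rows, vals = [], []
        for j in range(P):
            nz = np.nonzero(Xu[:, j])[0]
            indptr[j + 1] = indptr[j] + nz.size
            rows.append(nz)
            vals.append(Xu[nz, j])
        self.indptr = indptr
        self.rowidx = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
        self.vals = np.concatenate(vals) if vals else np.empty(0)

    def successes(self, y):
        """Per-unique-row success counts for one node's 0/1 outcome."""
        return np.bincount(self.inverse, weights=y, minlength=self.Xu.shape[0])


def prepare_design(X):
    """Group duplicate rows of a design matrix and precompute solver inputs."""
    Xu, inverse, cnt = np.unique(np.asarray(X, dtype=np.float64), axis=0,
                                 return_inverse=True, return_counts=True)
    return GroupedDesign(np.ascontiguousarray(Xu), cnt.astype(np.float64),
                         inverse.astype(np.int64))


def lambda_path(design, suc, n_lambda=100, ratio=1e-3):
    """Decreasing log-spaced penalty path from the data-derived lambda_max.

    lambda_max is the smallest penalty at which every penalized coefficient
    is zero: max_j |x_j'(y - ybar)| / N at the intercept-only fit.  Penalties
    are on the scale of the average negative log-likelihood.
    """
    N = design.N
    ybar = float(suc.sum()) / N
    g = design.Xu.T @ (suc - design.cnt * ybar) / N
    lam_max = float(np.max(np.abs(g)))
    if lam_max <= 0.0:
        lam_max = 1e-4
    # nudge above the KKT boundary so the first solution is exactly the
    # intercept-only fit regardless of round-off in the gradient
    lam_max *= 1.0 + 1e-9
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


@njit(cache=True)
def _log1pexp(z):
    if z > 0.0:
        return z + np.log1p(np.exp(-z))
    return np.log1p(np.exp(z))


@njit(cache=True)
def _sigmoid(z):
    if z >= 0.0:
        return 1.0 / (1.0 + np.exp(-z))
    e = np.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def _path_kernel(Xu, cnt, suc, G, indptr, rowidx, vals, lambdas, tol, max_outer):
    R, P = Xu.shape
    L = lambdas.shape[0]
    N = cnt.sum()
    quarterN = 4.0 * N

    beta = np.zeros(P + 1)  # last entry is the intercept
    ybar = suc.sum() / N
    beta[P] = np.log(ybar / (1.0 - ybar))

    eta = np.full(R, beta[P])
    g = np.empty(P + 1)
    u = np.empty(P + 1)
    resid = np.empty(R)

    coefs = np.empty((L, P))
    intercepts = np.empty(L)
    logliks = np.empty(L)
    nnz = np.zeros(L, dtype=np.int64)

    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            # gradient of the average negative log-likelihood at beta
            rsum = 0.0
            for r in range(R):
                rr = cnt[r] * _sigmoid(eta[r]) - suc[r]
                resid[r] = rr
                rsum += rr
            for j in range(P):
                s = 0.0
                for q in range(indptr[j], indptr[j + 1]):
                    s += vals[q] * resid[rowidx[q]]
                g[j] = s / N
            g[P] = rsum / N

            # coordinate descent on the quarter-bound quadratic majorizer
            for k in range(P + 1):
                u[k] = 0.0
            delta_outer = 0.0
            for _inner in range(200):
                delta_inner = 0.0
                for j in range(P + 1):
                    a = G[j, j] / quarterN
                    if a <= 0.0:
                        continue
                    c = g[j] + u[j] / quarterN
                    z = beta[j] - c / a
                    if j < P:
                        if z > lam / a:
                            t = z - lam / a
                        elif z < -lam / a:
                            t = z + lam / a
                        else:
                            t = 0.0
                    else:
                        t = z
                    d = t - beta[j]
                    if d != 0.0:
                        ad = abs(d)
                        if ad > delta_inner:
                            delta_inner = ad
                        for k in range(P + 1):
                            u[k] += G[k, j] * d
                        beta[j] = t
                if delta_inner > delta_outer:
                    delta_outer = delta_inner
                if delta_inner < 0.1 * tol:
                    break

            # refresh the linear predictor through the sparse columns
            for r in range(R):
                eta[r] = beta[P]
            for j in range(P):
                bj = beta[j]
                if bj != 0.0:
                    for q in range(indptr[j], indptr[j + 1]):
                        eta[rowidx[q]] += vals[q] * bj
            if delta_outer < tol:
                break

        ll = 0.0
        for r in range(R):
            ll += suc[r] * eta[r] - cnt[r] * _log1pexp(eta[r])
        logliks[li] = ll
        intercepts[li] = beta[P]
        c0 = 0
        for j in range(P):
            coefs[li, j] = beta[j]
            if beta[j] != 0.0:
                c0 += 1
        nnz[li] = c0

    return coefs, intercepts, logliks, nnz


def logistic_lasso_path(design, suc, lambdas, tol=1e-5, max_outer=1000):
    """Fit the lasso-logistic path for one node's outcome.

    Parameters
    ----------
    design : GroupedDesign shared by all nodes of a panel.
    suc : (R,) per-unique-row success counts (see GroupedDesign.successes).
    lambdas : (L,) strictly decreasing penalty levels.

    Returns
    -------
    coefs : (L, P) penalized coefficients.
    intercepts : (L,) unpenalized intercepts.
    logliks : (L,) total Bernoulli log-likelihood at each solution.
    nnz : (L,) number of nonzero penalized coefficients.
    """
    total = float(suc.sum())
    if total <= 0.0 or total >= design.N:
        raise ValueError("outcome has a single class")
    return _path_kernel(design.Xu, design.cnt, np.asarray(suc, dtype=np.float64),
                        design.G, design.indptr, design.rowidx, design.vals,
                        np.asarray(lambdas, dtype=np.float64), tol, max_outer)


def grouped_loglik(design, suc, beta, intercept):
    """Total Bernoulli log-likelihood of grouped data at given coefficients."""
    eta = design.Xu @ beta + intercept
    return float(np.sum(suc * eta - design.cnt * np.logaddexp(0.0, eta)))


@njit(cache=True)
def _refit_kernel(Xu, cnt, suc, tol, max_iter, cap):
    R, P = Xu.shape
    beta = np.zeros(P)
    b = 0.0
    N = cnt.sum()
    ybar = suc.sum() / N
    if 0.0 < ybar < 1.0:
        b = np.log(ybar / (1.0 - ybar))
    capped = False
    for _ in range(max_iter):
        eta = np.empty(R)
        for r in range(R):
            e = b
            for j in range(P):
                e += Xu[r, j] * beta[j]
            eta[r] = e
        w = np.empty(R)
        resid = np.empty(R)
        for r in range(R):
            p = _sigmoid(eta[r])
            w[r] = max(cnt[r] * p * (1.0 - p), 1e-10)
            resid[r] = cnt[r] * p - suc[r]
        H = np.empty((P + 1, P + 1))
        g = np.empty(P + 1)
        for j in range(P):
            s = 0.0
            for r in range(R):
                s += Xu[r, j] * resid[r]
            g[j] = s
        g[P] = resid.sum()
        for j in range(P):
            for k in range(j, P):
                s = 0.0
                for r in range(R):
                    s += Xu[r, j] * Xu[r, k] * w[r]
                H[j, k] = s
                H[k, j] = s
            s = 0.0
            for r in range(R):
                s += Xu[r, j] * w[r]
            H[j, P] = s
            H[P, j] = s
        H[P, P] = w.sum()
        for j in range(P + 1):
            H[j, j] += 1e-9
        step = np.linalg.solve(H, g)
        beta -= step[:P]
        b -= step[P]
        if np.max(np.abs(step)) < tol:
            break
        big = abs(b)
        for j in range(P):
            if abs(beta[j]) > big:
                big = abs(beta[j])
        if big > cap:
            capped = True
            break
    for j in range(P):
        if beta[j] > cap:
            beta[j] = cap
            capped = True
        elif beta[j] < -cap:
            beta[j] = -cap
            capped = True
    if b > cap:
        b = cap
        capped = True
    elif b < -cap:
        b = -cap
        capped = True
    return beta, b, capped


def logistic_refit(Xu, cnt, suc, tol=1e-9, max_iter=60, cap=15.0):
    """Unpenalized logistic regression by Newton iteration on grouped rows.

    Used for the data-splitting refits on small selected supports.  Under
    quasi-complete separation coefficients diverge; iteration stops once any
    coefficient magnitude exceeds `cap` and the result is clipped, with a
    flag so callers can mark the replicate.

    Returns (beta, intercept, capped_flag).
    """
    return _refit_kernel(np.ascontiguousarray(Xu, dtype=np.float64),
                         np.asarray(cnt, dtype=np.float64),
                         np.asarray(suc, dtype=np.float64), tol, max_iter, cap)
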