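"""Numba kernels for elastic-net regularized logistic regression.

Objective minimized (binomial deviance = -2 log-likelihood):

    (1/N) * Deviance(b0, beta) + lam * [ alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 ]

solved by IRLS + cyclic coordinate descent on the standardized design, with
step-halving so the objective trace is non-increasing by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_CLIP = 1e-5


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def objective(X, y, b0, beta, alpha, lam):
    N = X.shape[0]
    eta = b0 + X.dot(beta)
    dev = 0.0
    for i in range(N):
        e = eta[i]
        if e > 0.0:
            lse = e + np.log1p(np.exp(-e))
        else:
            lse = np.log1p(np.exp(e))
        dev += -2.0 * (y[i] * e - lse)
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += alpha * abs(beta[j]) + 0.5 * (1.0 - alpha) * beta[j] * beta[j]
    return dev / N + lam * pen


@njit(cache=True)
def cd_solve(X, y, alpha, lam, b0, beta, max_outer, tol):
    """One (alpha, lam) solve; returns (b0, beta, objective trace, converged)."""
    N, p = X.shape
    inner_tol = tol * 10.0
    if inner_tol < 1e-9:
        inner_tol = 1e-9
    trace = np.empty(max_outer + 1)
    obj = objective(X, y, b0, beta, alpha, lam)
    trace[0] = obj
    n_tr = 1
    converged = False
    for _ in range(max_outer):
        b0_old = b0
        beta_old = beta.copy()
        eta = b0 + X.dot(beta)
        pp = 1.0 / (1.0 + np.exp(-eta))
        for i in range(N):
            if pp[i] < P_CLIP:
                pp[i] = P_CLIP
            elif pp[i] > 1.0 - P_CLIP:
                pp[i] = 1.0 - P_CLIP
        w = pp * (1.0 - pp)
        r = (y - pp) / w  # working residual z - eta
        wxx = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(N):
                s += w[i] * X[i, j] * X[i, j]
            wxx[j] = s
        sw = w.sum()
        active = np.ones(p, dtype=np.bool_)

        def _sweep(use_active):
            maxd = 0.0
            num0 = 0.0
            for i in range(N):
                num0 += w[i] * r[i]
            d0 = num0 / sw
            nonlocal_b0 = d0  # numba: returned instead of closing over b0
            for i in range(N):
                r[i] -= d0
            if abs(d0) > maxd:
                maxd = abs(d0)
            for j in range(p):
                if use_active and not active[j]:
                    continue
                wxr = 0.0
                for i in range(N):
                    wxr += w[i] * X[i, j] * r[i]
                num = (2.0 / N) * (wxr + wxx[j] * beta[j])
                den = (2.0 / N) * wxx[j] + lam * (1.0 - alpha)
                if den <= 0.0:
                    bj = 0.0
                else:
                    bj = _soft(num, lam * alpha) / den
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    for i in range(N):
                        r[i] -= X[i, j] * d
                if abs(d) > maxd:
                    maxd = abs(d)
            return nonlocal_b0, maxd

        # glmnet-style: full sweep, then iterate the active (nonzero) set
        for _cycle in range(50):
            d0, maxd_full = _sweep(False)
            b0 += d0
            if maxd_full < inner_tol:
                break
            for j in range(p):
                active[j] = beta[j] != 0.0
            for _inner in range(200):
                d0, maxd = _sweep(True)
                b0 += d0
                if maxd < inner_tol:
                    break
        new_obj = objective(X, y, b0, beta, alpha, lam)
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 30:
            b0 = 0.5 * (b0 + b0_old)
            for j in range(p):
                beta[j] = 0.5 * (beta[j] + beta_old[j])
            new_obj = objective(X, y, b0, beta, alpha, lam)
            halvings += 1
        if new_obj > obj + 1e-12:
            b0 = b0_old
            beta = beta_old
            converged = True
            break
        trace[n_tr] = new_obj
        n_tr += 1
        if obj - new_obj < tol * (abs(obj) + 1e-12):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    return b0, beta, trace[:n_tr], converged


@njit(cache=True)
def path_fit(X, y, alpha, lams, max_outer, tol):
    """Warm-started fit along a descending lambda sequence (standardized X)."""
    N, p = X.shape
    L = lams.shape[0]
    B0 = np.empty(L)
    B = np.empty((L, p))
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    null_dev = objective(X, y, b0, beta, 1.0, 0.0)
    for k in range(L):
        b0, beta, _, _ = cd_solve(X, y, alpha, lams[k], b0, beta, max_outer, tol)
        B0[k] = b0
        for j in range(p):
            B[k, j] = beta[j]
        # stop descending once ~99% of the null deviance is explained
        # (separable tail); carry the last solution down the path
        if objective(X, y, b0, beta, 1.0, 0.0) < 0.01 * null_dev:
            for k2 in range(k + 1, L):
                B0[k2] = b0
                for j in range(p):
                    B[k2, j] = beta[j]
            break
    return B0, B


@njit(cache=True)
def cv_path_deviance(X, y, alpha, lams, fold_ids, n_folds, max_outer, tol):
    """Held-out per-observation deviance for every lambda on the path.

    Each fold standardizes its own training rows.  Returns (L, N) deviances.
    """
    N, p = X.shape
    L = lams.shape[0]
    dev = np.zeros((L, N))
    for f in range(n_folds):
        n_tr = 0
        for i in range(N):
            if fold_ids[i] != f:
                n_tr += 1
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        k = 0
        for i in range(N):
            if fold_ids[i] != f:
                for j in range(p):
                    Xtr[k, j] = X[i, j]
                ytr[k] = y[i]
                k += 1
        mu = np.empty(p)
        sd = np.empty(p)
        for j in range(p):
            m = Xtr[:, j].mean()
            s = Xtr[:, j].std()
            mu[j] = m
            sd[j] = s if s > 0.0 else 1.0
            for i in range(n_tr):
                Xtr[i, j] = (Xtr[i, j] - m) / sd[j]
        B0, B = path_fit(Xtr, ytr, alpha, lams, max_outer, tol)
        for i in range(N):
            if fold_ids[i] != f:
                continue
            for k2 in range(L):
                eta = B0[k2]
                for j in range(p):
                    eta += (X[i, j] - mu[j]) / sd[j] * B[k2, j]
                if eta > 0.0:
                    lse = eta + np.log1p(np.exp(-eta))
                else:
                    lse = np.log1p(np.exp(eta))
                dev[k2, i] = -2.0 * (y[i] * eta - lse)
    return dev
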