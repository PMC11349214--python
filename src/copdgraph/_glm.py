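"""Minimal dense GLM fits used by the conditional-independence tests.

These are purpose-built for small design matrices called tens of thousands
of times during skeleton pruning, where generic model APIs dominate the
run time.  Only what the likelihood-ratio tests need is provided: residual
sums of squares for Gaussian responses and maximized log-likelihoods for
multinomial responses, together with design ranks for degree-of-freedom
accounting.  All solves run on d x d Gram matrices (d is a handful of
columns), with eigenvalue-based rank detection for collinear designs, and
Newton solves accept a warm start so nested models can reuse work.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import linalg


def drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Remove linearly dependent columns (pivoted-QR rank reveal)."""
    if X.shape[1] == 0:
        return X
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if len(diag) == 0:
        return X[:, :0]
    rank = int((diag > tol * diag[0]).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep]


def _gram_rank(G: np.ndarray, tol: float = 1e-9) -> int:
    w = np.linalg.eigvalsh(G)
    top = w[-1] if len(w) else 0.0
    if top <= 0:
        return 0
    return int((w > tol * top).sum())


def gaussian_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares residual sum of squares and design rank (Gram-based)."""
    if X.shape[1] == 0:
        return float(y @ y), 0
    G = X.T @ X
    c = X.T @ y
    rank = _gram_rank(G)
    if rank == X.shape[1]:
        try:
            beta = linalg.cho_solve(linalg.cho_factor(G), c)
        except linalg.LinAlgError:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(y @ y - c @ beta)
    return max(rss, 0.0), rank


@njit(cache=True, fastmath=False)
def _newton_core(X, Yk, B, ridge, max_iter, tol):  # pragma: no cover - jitted
    n, d = X.shape
    k = Yk.shape[1]
    ll_prev = -1e300
    ll = 0.0
    eta = np.empty((n, k))
    P = np.empty((n, k))
    for _ in range(max_iter):
        eta = np.dot(X, B)
        ll = 0.0
        for i in range(n):
            m = 0.0
            for a in range(k):
                if eta[i, a] > m:
                    m = eta[i, a]
            denom = np.exp(-m)
            for a in range(k):
                P[i, a] = np.exp(eta[i, a] - m)
                denom += P[i, a]
            for a in range(k):
                P[i, a] /= denom
                ll += Yk[i, a] * eta[i, a]
            ll -= m + np.log(denom)
        pen = 0.0
        for j in range(d):
            for a in range(k):
                pen += B[j, a] * B[j, a]
        ll -= 0.5 * ridge * pen
        if ll - ll_prev < tol * (abs(ll) + 1.0) and ll >= ll_prev:
            break
        ll_prev = ll
        G = X.T @ (Yk - P) - ridge * B
        H = np.zeros((d * k, d * k))
        Xw = np.empty((n, d))
        for a in range(k):
            for b in range(a, k):
                for i in range(n):
                    w = P[i, a] * ((1.0 if a == b else 0.0) - P[i, b])
                    for j1 in range(d):
                        Xw[i, j1] = X[i, j1] * w
                blk = np.dot(Xw.T, X)
                for j1 in range(d):
                    for j2 in range(d):
                        H[a * d + j1, b * d + j2] = blk[j1, j2]
                        if b != a:
                            H[b * d + j1, a * d + j2] = blk[j1, j2]
        for j in range(d * k):
            H[j, j] += ridge
        g = np.empty(d * k)
        for a in range(k):
            for j in range(d):
                g[a * d + j] = G[j, a]
        step = np.linalg.solve(H, g)
        for a in range(k):
            for j in range(d):
                B[j, a] += step[a * d + j]
    # final unpenalized log-likelihood
    eta = np.dot(X, B)
    ll = 0.0
    for i in range(n):
        m = 0.0
        for a in range(k):
            if eta[i, a] > m:
                m = eta[i, a]
        denom = np.exp(-m)
        for a in range(k):
            denom += np.exp(eta[i, a] - m)
        for a in range(k):
            ll += Yk[i, a] * eta[i, a]
        ll -= m + np.log(denom)
    return ll, B


def multinomial_loglik(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = 1e-6,
    max_iter: int = 30,
    tol: float = 1e-8,
    warm_start: np.ndarray | None = None,
) -> tuple[float, int, np.ndarray]:
    """Maximized log-likelihood of a multinomial logit.

    ``Y`` is an (n, L) one-hot response over the observed levels (L >= 2);
    logits are reference-coded against the first level.  A tiny ridge keeps
    the Newton steps defined under (quasi-)separation; its effect on the
    log-likelihood is negligible at test scale.  Returns (loglik, design
    rank, coefficient matrix); pass the coefficients of a nested model
    (padded with zero rows) as ``warm_start`` to cut Newton iterations.
    """
    n, d_in = X.shape
    if d_in:
        rank = _gram_rank(X.T @ X)
        if rank < d_in:
            X = drop_collinear(X)
            warm_start = None
    d = X.shape[1]
    L = Y.shape[1]
    k = L - 1
    if d == 0 or k == 0:
        counts = Y.sum(axis=0)
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float((counts[p > 0] * np.log(p[p > 0])).sum())
        return ll, 0, np.zeros((d, k))
    if warm_start is not None and warm_start.shape == (d, k):
        B = np.ascontiguousarray(warm_start, dtype=np.float64)
    else:
        B = np.zeros((d, k))
    Yk = np.ascontiguousarray(Y[:, 1:], dtype=np.float64)
    X = np.ascontiguousarray(X, dtype=np.float64)
    try:
        ll, B = _newton_core(X, Yk, B, ridge, max_iter, tol)
    except Exception:  # singular Hessian despite ridge: drop to lstsq path
        ll, B = _newton_numpy(X, Yk, B * 0.0, ridge, max_iter, tol)
    return float(ll), X.shape[1], B


def _newton_numpy(X, Yk, B, ridge, max_iter, tol):
    """Plain-numpy Newton fallback (lstsq steps) for degenerate Hessians."""
    n, d = X.shape
    k = Yk.shape[1]
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = X @ B
        m = np.maximum(eta.max(axis=1), 0.0)
        E = np.exp(eta - m[:, None])
        denom = np.exp(-m) + E.sum(axis=1)
        lse = m + np.log(denom)
        ll = float((Yk * eta).sum() - lse.sum()) - 0.5 * ridge * float((B * B).sum())
        if ll - ll_prev < tol * (abs(ll) + 1.0) and ll >= ll_prev:
            break
        ll_prev = ll
        P = E / denom[:, None]
        G = X.T @ (Yk - P) - ridge * B
        H = np.empty((d * k, d * k))
        for a in range(k):
            for b in range(a, k):
                w = P[:, a] * ((a == b) - P[:, b])
                blk = X.T @ (X * w[:, None])
                H[a * d : (a + 1) * d, b * d : (b + 1) * d] = blk
                if b != a:
                    H[b * d : (b + 1) * d, a * d : (a + 1) * d] = blk
        H[np.diag_indices_from(H)] += ridge
        step = np.linalg.lstsq(H, G.T.reshape(-1), rcond=None)[0]
        B = B + step.reshape(k, d).T
    eta = X @ B
    m = np.maximum(eta.max(axis=1), 0.0)
    lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    return float((Yk * eta).sum() - lse.sum()), B
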