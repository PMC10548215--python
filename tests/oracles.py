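"""Independent reference implementations used only as test oracles.

These are deliberately literal, loop-based transcriptions of the published
algorithm descriptions, kept free of the vectorized machinery they check.
"""

import numpy as np


def rrelieff_literal(X, y, k, sigma, m, rng):
    """Literal RReliefF (regression Relief) with expRank neighbor weights.

    One random instance per iteration, k nearest neighbors by Manhattan
    distance on min-max-scaled attributes, rank weights exp(-(rank/sigma)^2)
    normalized to sum 1.  Consumes one rng.integers(0, n) draw per
    iteration, in order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    Xs[:, hi == lo] = 0.0
    ys = (y - y.min()) / (y.max() - y.min())

    w_rank = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    w_rank = w_rank / w_rank.sum()

    NdC = 0.0
    NdA = np.zeros(p)
    NdCdA = np.zeros(p)
    for _ in range(m):
        i = int(rng.integers(0, n))
        dists = np.abs(Xs - Xs[i]).sum(axis=1)
        order = np.argsort(dists, kind="stable")
        neighbors = [j for j in order if j != i][:k]
        for rank, j in enumerate(neighbors):
            w = w_rank[rank]
            dy = abs(ys[j] - ys[i])
            NdC += dy * w
            for a in range(p):
                da = abs(Xs[j, a] - Xs[i, a])
                NdA[a] += da * w
                NdCdA[a] += dy * da * w
    return NdCdA / NdC - (NdA - NdCdA) / (m - NdC)


def nipals_pls1_literal(X, y, n_components):
    """Literal orthogonal-scores (NIPALS) PLS1: mean centering, unit-norm
    weights, X-deflation by t p'.  Returns (coef, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = y.mean()
    E = X - xm
    f = y - ym
    W, P, q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        w = w / np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        qh = (f @ t) / (t @ t)
        E = E - np.outer(t, p)
        f = f - qh * t
        W.append(w)
        P.append(p)
        q.append(qh)
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.asarray(q)
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, ym - xm @ coef
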