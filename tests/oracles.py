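"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own fitting code paths: the logistic
oracle is a coarse-to-fine grid search over the log-likelihood surface, the
BH oracle is the literal min-over-larger-ranks definition, and the AUC
oracle counts all case-control pairs.
"""

import numpy as np


def loglik(beta, X, y, offset=None):
    eta = X @ np.asarray(beta, dtype=float)
    if offset is not None:
        eta = eta + offset
    s = (2.0 * y - 1.0) * eta
    return float(-np.sum(np.logaddexp(0.0, -s)))


def grid_logistic_2d(X, y, offset=None, lo=-5.0, hi=5.0, rounds=4, pts=201):
    """Maximize a 2-parameter Bernoulli log-likelihood by nested grid search
    (final resolution ~ (hi-lo) / pts**rounds < 1e-3)."""
    y = np.asarray(y, dtype=float)
    c0 = c1 = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    for _ in range(rounds):
        b0 = np.linspace(c0 - half, c0 + half, pts)
        b1 = np.linspace(c1 - half, c1 + half, pts)
        B = np.stack(np.meshgrid(b0, b1, indexing="ij"), axis=-1).reshape(-1, 2)
        eta = B @ X.T
        if offset is not None:
            eta = eta + offset[None, :]
        ll = -np.sum(np.logaddexp(0.0, -(2.0 * y - 1.0)[None, :] * eta), axis=1)
        best = B[np.argmax(ll)]
        c0, c1 = best
        half /= (pts - 1) / 4.0  # shrink window, keep overlap
    return np.array([c0, c1]), loglik([c0, c1], X, y, offset)


def bh_bruteforce(pvalues, m):
    """Literal step-up definition: adjusted(i) = min_{j>=i} p(j)*m/j, cap 1."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    n = len(p)
    adj = np.empty(n)
    for i in range(n):
        adj[i] = min(min(ranked[j] * m / (j + 1) for j in range(i, n)), 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def auc_pair_counting(scores, labels):
    """All-pairs concordance count; ties worth one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))
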