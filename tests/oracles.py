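"""Independent reference implementations used as test oracles.

Deliberately naive (exhaustive enumeration, dense linear algebra) and
written without touching the package's own code paths.
"""

from itertools import combinations

import numpy as np


def brute_force_maximal_cliques(adjacency, min_size=2):
    """All maximal complete subgraphs of size >= min_size, by checking every
    vertex subset. Exponential; n <= ~15 only."""
    A = np.asarray(adjacency, bool)
    n = A.shape[0]
    complete = []
    for size in range(2, n + 1):
        for subset in combinations(range(n), size):
            if all(A[i, j] for i, j in combinations(subset, 2)):
                complete.append(frozenset(subset))
    maximal = [c for c in complete if not any(c < d for d in complete)]
    return sorted(tuple(sorted(c)) for c in maximal if len(c) >= min_size)


def dense_nam_loglik(model_type, rho, beta, sigma2, y, X, W1=None, W2=None):
    """Network autocorrelation log-likelihood via dense determinants and
    explicit residual algebra."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.size
    beta = np.asarray(beta, float)

    def dense(W):
        return np.asarray(W.todense()) if hasattr(W, "todense") else np.asarray(W, float)

    logdet = 0.0
    if model_type == "effects":
        A1 = np.eye(n) - rho * dense(W1)
        logdet += np.log(np.linalg.det(A1))
        resid = A1 @ y - X @ beta
    elif model_type == "disturbances":
        A2 = np.eye(n) - rho * dense(W2)
        logdet += np.log(np.linalg.det(A2))
        resid = A2 @ (y - X @ beta)
    else:
        rho1, rho2 = rho
        A1 = np.eye(n) - rho1 * dense(W1)
        A2 = np.eye(n) - rho2 * dense(W2)
        logdet += np.log(np.linalg.det(A1)) + np.log(np.linalg.det(A2))
        resid = A2 @ (A1 @ y - X @ beta)
    return (
        -0.5 * n * np.log(2 * np.pi * sigma2)
        + logdet
        - 0.5 * resid @ resid / sigma2
    )


def conjugate_beta_posterior(y, X, Zs, variances, sigma2_e):
    """Closed-form Gaussian posterior of beta (flat prior) with known
    variance components: y ~ N(X beta, V), V = sigma2_e I + sum s2_k Z_k Z_k'."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = y.size
    V = sigma2_e * np.eye(n)
    for Z, s2 in zip(Zs, variances):
        Zd = np.asarray(Z.todense()) if hasattr(Z, "todense") else np.asarray(Z, float)
        V += s2 * (Zd @ Zd.T)
    Vinv = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vinv @ X)
    mean = cov @ X.T @ Vinv @ y
    return mean, cov


def random_membership_map(rng, n, k, max_memberships=4):
    """Random multiple-membership structure as a membership-index list."""
    member_index = []
    for _ in range(n):
        m = rng.integers(0, min(max_memberships, k) + 1)
        member_index.append(sorted(rng.choice(k, size=m, replace=False)) if m else [])
    return member_index
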