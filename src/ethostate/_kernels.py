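"""Low-level forward / Viterbi recursions.

Compiled with numba when available; the pure-NumPy fallbacks have identical
signatures and semantics so everything above this module is agnostic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def forward_loglik_kernel(log_b: np.ndarray, tpm: np.ndarray, delta: np.ndarray) -> float:
    """Scaled forward recursion.

    Parameters
    ----------
    log_b : (T, K) per-window emission log-densities.
    tpm : (K, K) row-stochastic transition matrix.
    delta : (K,) initial distribution.

    Returns the exact log-likelihood; per-step rescaling (max-shift plus
    normalisation) keeps the recursion in a safe floating range.
    """
    T, K = log_b.shape
    ll = 0.0
    alpha = np.empty(K)
    m = log_b[0].max()
    for k in range(K):
        alpha[k] = delta[k] * np.exp(log_b[0, k] - m)
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf
    alpha /= c
    ll += np.log(c) + m
    tmp = np.empty(K)
    for t in range(1, T):
        m = log_b[t].max()
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[i] * tpm[i, j]
            tmp[j] = s * np.exp(log_b[t, j] - m)
        c = tmp.sum()
        if c <= 0.0:
            return -np.inf
        for j in range(K):
            alpha[j] = tmp[j] / c
        ll += np.log(c) + m
    return ll


@njit(cache=False)
def forward_backward_kernel(
    log_b: np.ndarray, tpm: np.ndarray, delta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaled forward-backward pass.

    Returns ``(loglik, gamma, xi_sum)`` where ``gamma[t, k]`` is the
    posterior state probability of window t and ``xi_sum[i, j]`` the
    expected transition count from i to j over the track. Same scaling
    scheme as :func:`forward_loglik_kernel`.
    """
    T, K = log_b.shape
    bs = np.empty((T, K))
    c = np.empty(T)
    alpha = np.empty((T, K))
    ll = 0.0
    for t in range(T):
        m = log_b[t].max()
        for k in range(K):
            bs[t, k] = np.exp(log_b[t, k] - m)
        ll += m
    for k in range(K):
        alpha[0, k] = delta[k] * bs[0, k]
    c[0] = alpha[0].sum()
    if c[0] <= 0.0:
        return -np.inf, np.zeros((T, K)), np.zeros((K, K))
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * tpm[i, j]
            alpha[t, j] = s * bs[t, j]
        c[t] = alpha[t].sum()
        if c[t] <= 0.0:
            return -np.inf, np.zeros((T, K)), np.zeros((K, K))
        alpha[t] /= c[t]
    ll += np.log(c).sum()
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += tpm[i, j] * bs[t + 1, j] * beta[t + 1, j]
            beta[t, i] = s / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi[i, j] += (
                    alpha[t, i] * tpm[i, j] * bs[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )
    gamma = alpha * beta
    # guard against scaling drift: posteriors are probabilities per window
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    return ll, gamma, xi


@njit(cache=False)
def viterbi_kernel(log_b: np.ndarray, log_tpm: np.ndarray, log_delta: np.ndarray) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    T, K = log_b.shape
    phi = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        phi[0, k] = log_delta[k] + log_b[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = phi[t - 1, i] + log_tpm[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            phi[t, j] = best + log_b[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if phi[T - 1, k] > best:
            best = phi[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
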