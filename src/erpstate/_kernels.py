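"""Numerical inner loops for the HMM recursions.

The forward/backward and Viterbi recursions are O(T*K^2) sequential loops,
so they are compiled with numba when available.  The pure-Python bodies are
kept numba-compatible; if numba is missing the same functions run (slowly)
under CPython.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def forward_backward_kernel(B, pi, A):
    """Scaled forward-backward on likelihoods B (T x K, already exp-shifted).

    Returns (gamma, xi_sum, log_c_sum, ok) where log_c_sum is the sum of the
    log scaling constants (the shift terms are added back by the caller) and
    ok is False when some time point had zero total likelihood.
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    # forward
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    if s <= 0.0:
        return alpha, np.zeros((K, K)), 0.0, False
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * A[j, k]
            a *= B[t, k]
            alpha[t, k] = a
            s += a
        if s <= 0.0:
            return alpha, np.zeros((K, K)), 0.0, False
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    # backward + pairwise expected counts
    for k in range(K):
        beta[T - 1, k] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        for j in range(K):
            b = 0.0
            for k in range(K):
                b += A[j, k] * B[t + 1, k] * beta[t + 1, k]
            beta[t, j] = b / c[t + 1]
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j] * A[j, k] * B[t + 1, k] * beta[t + 1, k] / c[t + 1]
                )

    gamma = alpha * beta
    # normalise each row (guards round-off; rows already sum to ~1)
    for t in range(T):
        s = 0.0
        for k in range(K):
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    log_c_sum = 0.0
    for t in range(T):
        log_c_sum += np.log(c[t])
    return gamma, xi_sum, log_c_sum, True


@njit(cache=True)
def viterbi_kernel(logB, log_pi, log_A):
    """Max-product recursion in log space; ties broken toward the lower index."""
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_A[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_A[j, k]
                if v > best:  # strict: keeps the lowest index on ties
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


@njit(cache=True)
def markov_sample_kernel(cum_early, cum_late, late_mask, s0, u):
    """Sample a time-inhomogeneous Markov chain.

    cum_early / cum_late are K x K row-wise cumulative transition
    probabilities; late_mask[t] selects which matrix governs the step into
    time t; s0 is the initial state and u holds T-1 uniform draws.
    """
    T = late_mask.shape[0]
    K = cum_early.shape[0]
    path = np.empty(T, dtype=np.int64)
    path[0] = s0
    for t in range(1, T):
        cum = cum_late if late_mask[t] else cum_early
        r = u[t - 1]
        s = path[t - 1]
        nxt = K - 1
        for k in range(K):
            if r < cum[s, k]:
                nxt = k
                break
        path[t] = nxt
    return path
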