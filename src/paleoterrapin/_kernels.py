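"""Scaled forward-backward recursions for the coalescent HMM.

Jit-compiled with numba when available; a numpy fallback keeps tiny oracle
instances and environments without a working jit functional.
"""

from __future__ import annotations

import numpy as np


def _fb_py(obs, P, E, pi):
    T = obs.shape[0]
    K = P.shape[0]
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = pi * E[:, obs[0]]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P) * E[:, obs[t]]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    loglik = float(np.sum(np.log(scale)))

    beta = np.ones(K)
    counts_emit = np.zeros((K, 3))
    A = np.zeros((K, K))
    gamma_last = alpha[T - 1] * beta
    counts_emit[:, obs[T - 1]] += gamma_last
    for t in range(T - 2, -1, -1):
        eb = E[:, obs[t + 1]] * beta
        A += np.outer(alpha[t], eb / scale[t + 1]) * P
        beta = (P @ eb) / scale[t + 1]
        g = alpha[t] * beta
        counts_emit[:, obs[t]] += g
    gamma0 = alpha[0] * beta
    return loglik, counts_emit, A, gamma0


def _posteriors_py(obs, P, E, pi):
    T = obs.shape[0]
    K = P.shape[0]
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = pi * E[:, obs[0]]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P) * E[:, obs[t]]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    gamma = np.empty((T, K))
    beta = np.ones(K)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        eb = E[:, obs[t + 1]] * beta
        beta = (P @ eb) / scale[t + 1]
        gamma[t] = alpha[t] * beta
    return float(np.sum(np.log(scale))), gamma


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _fb_nb(obs, P, E, pi):  # type: ignore[misc]
        T = obs.shape[0]
        K = P.shape[0]
        alpha = np.empty((T, K))
        scale = np.empty(T)
        s = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * E[k, obs[0]]
            s += alpha[0, k]
        scale[0] = s
        for k in range(K):
            alpha[0, k] /= s
        for t in range(1, T):
            s = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * P[i, j]
                acc *= E[j, obs[t]]
                alpha[t, j] = acc
                s += acc
            scale[t] = s
            for j in range(K):
                alpha[t, j] /= s
        loglik = 0.0
        for t in range(T):
            loglik += np.log(scale[t])

        beta = np.ones(K)
        counts_emit = np.zeros((K, 3))
        A = np.zeros((K, K))
        for k in range(K):
            counts_emit[k, obs[T - 1]] += alpha[T - 1, k]
        eb = np.empty(K)
        newbeta = np.empty(K)
        for t in range(T - 2, -1, -1):
            sc = scale[t + 1]
            for j in range(K):
                eb[j] = E[j, obs[t + 1]] * beta[j] / sc
            for i in range(K):
                ai = alpha[t, i]
                acc = 0.0
                for j in range(K):
                    pij = P[i, j]
                    A[i, j] += ai * eb[j] * pij
                    acc += pij * eb[j]
                newbeta[i] = acc
            for i in range(K):
                beta[i] = newbeta[i]
                counts_emit[i, obs[t]] += alpha[t, i] * beta[i]
        gamma0 = np.empty(K)
        for k in range(K):
            gamma0[k] = alpha[0, k] * beta[k]
        return loglik, counts_emit, A, gamma0

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def forward_backward_counts(obs, P, E, pi):
    """Log-likelihood plus expected emission/transition/initial counts."""
    obs = np.ascontiguousarray(obs, dtype=np.int8)
    if HAVE_NUMBA and obs.shape[0] > 2000:
        return _fb_nb(obs, np.ascontiguousarray(P), np.ascontiguousarray(E), np.ascontiguousarray(pi))
    return _fb_py(obs, P, E, pi)


def posterior_marginals(obs, P, E, pi):
    """Log-likelihood and per-bin posterior state probabilities."""
    obs = np.ascontiguousarray(obs, dtype=np.int8)
    return _posteriors_py(obs, P, E, pi)
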