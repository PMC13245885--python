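"""Numba-compiled scaled forward-backward and Viterbi recursions.

The chain has 3 states; recursions use per-position scaling, which is
numerically equivalent to log-space evaluation but branch-free and fast for
genome-length sequences.
"""

import numba
import numpy as np

_EXP_FLOOR = 1e-300


@numba.njit(cache=True)
def forward_backward_kernel(logb, log_pi, log_gamma):
    """Scaled forward-backward for a 3-state chain.

    Parameters are the (M, 3) emission log-densities, log initial
    probabilities and (3, 3) log transition matrix.  Returns
    (rho, xi, loglik): smoothed state posteriors (M, 3), pairwise posteriors
    (M-1, 3, 3) and the observed-data log-likelihood.
    """
    M = logb.shape[0]
    R = 3
    # stabilize emissions per position
    shift = np.empty(M)
    b = np.empty((M, R))
    for j in range(M):
        m = logb[j, 0]
        for r in range(1, R):
            if logb[j, r] > m:
                m = logb[j, r]
        shift[j] = m
        for r in range(R):
            b[j, r] = np.exp(logb[j, r] - m)
    pi = np.exp(log_pi)
    gamma = np.exp(log_gamma)

    alpha = np.empty((M, R))
    c = np.empty(M)
    s = 0.0
    for r in range(R):
        alpha[0, r] = pi[r] * b[0, r]
        s += alpha[0, r]
    if s < _EXP_FLOOR:
        s = _EXP_FLOOR
    c[0] = s
    for r in range(R):
        alpha[0, r] /= s
    for j in range(1, M):
        s = 0.0
        for r in range(R):
            a = 0.0
            for q in range(R):
                a += alpha[j - 1, q] * gamma[q, r]
            a *= b[j, r]
            alpha[j, r] = a
            s += a
        if s < _EXP_FLOOR:
            s = _EXP_FLOOR
        c[j] = s
        for r in range(R):
            alpha[j, r] /= s

    beta = np.empty((M, R))
    for r in range(R):
        beta[M - 1, r] = 1.0
    for j in range(M - 2, -1, -1):
        for r in range(R):
            a = 0.0
            for q in range(R):
                a += gamma[r, q] * b[j + 1, q] * beta[j + 1, q]
            beta[j, r] = a / c[j + 1]

    rho = np.empty((M, R))
    for j in range(M):
        s = 0.0
        for r in range(R):
            rho[j, r] = alpha[j, r] * beta[j, r]
            s += rho[j, r]
        for r in range(R):
            rho[j, r] /= s

    xi = np.empty((M - 1, R, R))
    for j in range(1, M):
        s = 0.0
        for r in range(R):
            for q in range(R):
                v = alpha[j - 1, r] * gamma[r, q] * b[j, q] * beta[j, q] / c[j]
                xi[j - 1, r, q] = v
                s += v
        for r in range(R):
            for q in range(R):
                xi[j - 1, r, q] /= s

    loglik = 0.0
    for j in range(M):
        loglik += np.log(c[j]) + shift[j]
    return rho, xi, loglik


@numba.njit(cache=True)
def viterbi_kernel(logb, log_pi, log_gamma):
    """Most probable state path; ties break toward the lower state index."""
    M = logb.shape[0]
    R = 3
    score = np.empty((M, R))
    back = np.zeros((M, R), dtype=np.int64)
    for r in range(R):
        score[0, r] = log_pi[r] + logb[0, r]
    for j in range(1, M):
        for r in range(R):
            best = score[j - 1, 0] + log_gamma[0, r]
            arg = 0
            for q in range(1, R):
                v = score[j - 1, q] + log_gamma[q, r]
                if v > best:  # strict: ties keep the lower q
                    best = v
                    arg = q
            score[j, r] = best + logb[j, r]
            back[j, r] = arg
    path = np.empty(M, dtype=np.int64)
    best = score[M - 1, 0]
    arg = 0
    for r in range(1, R):
        if score[M - 1, r] > best:
            best = score[M - 1, r]
            arg = r
    path[M - 1] = arg
    for j in range(M - 2, -1, -1):
        path[j] = back[j + 1, path[j + 1]]
    return path, best
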