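"""Linear-chain CRF primitives in log space.

Transition matrices are (L+2) x (L+2) with the start state at index L and the
stop state at index L+1; entry [i, j] scores a transition i -> j.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def _check(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    emissions = np.asarray(emissions)
    if emissions.ndim != 2:
        raise ValueError("emissions must be 2-D (n, L)")
    n, L = emissions.shape
    if transitions.shape != (L + 2, L + 2):
        raise ValueError(
            f"transitions must be ({L + 2}, {L + 2}) for {L} labels, got {transitions.shape}"
        )
    return n, L


def crf_score(emissions: np.ndarray, transitions: np.ndarray, labels) -> float:
    """Unnormalized path score: emissions + transitions incl. start/stop."""
    n, L = _check(emissions, transitions)
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels length must match emissions")
    start, stop = L, L + 1
    score = transitions[start, labels[0]] + emissions[0, labels[0]]
    for t in range(1, n):
        score += transitions[labels[t - 1], labels[t]] + emissions[t, labels[t]]
    score += transitions[labels[-1], stop]
    return float(score)


def crf_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all label paths of exp(path score), by forward recursion."""
    n, L = _check(emissions, transitions)
    start, stop = L, L + 1
    alpha = transitions[start, :L] + emissions[0]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + transitions[:L, :L], axis=0) + emissions[t]
    return float(logsumexp(alpha + transitions[:L, stop]))


def crf_forward_backward(emissions: np.ndarray, transitions: np.ndarray):
    """Node marginals (n, L), pairwise marginals (n-1, L, L), and log Z.

    Pairwise marginals are P(y_t = i, y_{t+1} = j | X).
    """
    n, L = _check(emissions, transitions)
    start, stop = L, L + 1
    T = transitions[:L, :L]
    alphas = np.empty((n, L))
    alphas[0] = transitions[start, :L] + emissions[0]
    for t in range(1, n):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + T, axis=0) + emissions[t]
    logz = float(logsumexp(alphas[-1] + transitions[:L, stop]))

    betas = np.empty((n, L))
    betas[-1] = transitions[:L, stop]
    for t in range(n - 2, -1, -1):
        betas[t] = logsumexp(T + (emissions[t + 1] + betas[t + 1])[None, :], axis=1)

    node_marg = np.exp(alphas + betas - logz)
    pair_marg = np.empty((max(n - 1, 0), L, L))
    for t in range(n - 1):
        logm = (alphas[t][:, None] + T + (emissions[t + 1] + betas[t + 1])[None, :]) - logz
        pair_marg[t] = np.exp(logm)
    return node_marg, pair_marg, logz


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray) -> list[int]:
    """Highest-scoring label path; ties resolve to the lowest label index."""
    n, L = _check(emissions, transitions)
    start, stop = L, L + 1
    score = transitions[start, :L] + emissions[0]
    backptr = np.empty((n, L), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + transitions[:L, :L]
        backptr[t] = np.argmax(cand, axis=0)  # first (lowest-index) argmax
        score = cand[backptr[t], np.arange(L)] + emissions[t]
    score = score + transitions[:L, stop]
    best = int(np.argmax(score))
    path = [best]
    for t in range(n - 1, 0, -1):
        best = int(backptr[t, best])
        path.append(best)
    return path[::-1]


def crf_log_likelihood_grad(emissions: np.ndarray, transitions: np.ndarray, labels):
    """log P(Y|X) and its gradients w.r.t. emissions and transitions.

    grad(log P) = observed sufficient statistics - expected ones.
    """
    n, L = _check(emissions, transitions)
    start, stop = L, L + 1
    labels = list(labels)
    node_marg, pair_marg, logz = crf_forward_backward(emissions, transitions)
    loglik = crf_score(emissions, transitions, labels) - logz

    d_em = -node_marg
    d_em[np.arange(n), labels] += 1.0

    d_tr = np.zeros_like(transitions)
    d_tr[start, :L] -= node_marg[0]
    d_tr[start, labels[0]] += 1.0
    d_tr[:L, stop] -= node_marg[-1]
    d_tr[labels[-1], stop] += 1.0
    if n > 1:
        d_tr[:L, :L] -= pair_marg.sum(axis=0)
        for t in range(1, n):
            d_tr[labels[t - 1], labels[t]] += 1.0
    return float(loglik), d_em, d_tr
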