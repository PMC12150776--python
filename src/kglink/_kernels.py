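"""Numba kernels for random walks and stochastic embedding training.

All kernels are single-threaded and seed their RNG internally, so a fixed
seed yields bit-identical output across runs.  Noise distributions are
sampled in O(1) through alias tables; the sigmoid and its log come from a
lookup table over [-8, 8] (scores outside the range saturate), the standard
word2vec-style approximation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TABLE_SIZE = 2048
_MAX_SCORE = 8.0
_X = np.linspace(-_MAX_SCORE, _MAX_SCORE, _TABLE_SIZE)
_SIG_TABLE = 1.0 / (1.0 + np.exp(-_X))
_LOG_SIG_TABLE = np.log(_SIG_TABLE)
_LOG_NEG_TABLE = np.log(1.0 - _SIG_TABLE)
_SCALE = (_TABLE_SIZE - 1) / (2.0 * _MAX_SCORE)


def build_alias(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alias-method tables for O(1) sampling of a discrete distribution."""
    p = np.asarray(probs, dtype=np.float64)
    if p.sum() <= 0:
        raise ValueError("distribution has no mass")
    n = len(p)
    scaled = p * (n / p.sum())
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    while small and large:
        s = small.pop()
        l = large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for i in small + large:
        prob[i] = 1.0
    return prob, alias


@njit(cache=True)
def _contains(indices, lo, hi, value):
    """Binary search for ``value`` in the sorted slice ``indices[lo:hi]``."""
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] < value:
            lo = mid + 1
        else:
            hi = mid
    return lo < len(indices) and indices[lo] == value


@njit(cache=True)
def _alias_draw(prob, alias):
    i = np.random.randint(prob.shape[0])
    if np.random.random() < prob[i]:
        return i
    return alias[i]


@njit(cache=True)
def _sig_index(score):
    if score >= _MAX_SCORE:
        return _TABLE_SIZE - 1
    if score <= -_MAX_SCORE:
        return 0
    return int((score + _MAX_SCORE) * _SCALE)


@njit(cache=True)
def walk_kernel(indptr, indices, starts, walk_length, return_weight,
                explore_weight, seed):
    """Second-order biased random walks over a CSR adjacency.

    Per-step unnormalized weights follow the node2vec rule: ``return_weight``
    for stepping back to the previous node, 1 for a candidate adjacent to the
    previous node, ``explore_weight`` otherwise.  The first step is uniform.
    """
    np.random.seed(seed)
    n_walks = starts.shape[0]
    out = np.full((n_walks, walk_length), -1, dtype=np.int64)
    for w in range(n_walks):
        cur = starts[w]
        out[w, 0] = cur
        prev = -1
        for step in range(1, walk_length):
            s = indptr[cur]
            e = indptr[cur + 1]
            deg = e - s
            if deg == 0:
                break
            if prev < 0:
                nxt = indices[s + np.random.randint(deg)]
            else:
                ps = indptr[prev]
                pe = indptr[prev + 1]
                total = 0.0
                cum = np.empty(deg, dtype=np.float64)
                for i in range(deg):
                    cand = indices[s + i]
                    if cand == prev:
                        wgt = return_weight
                    elif _contains(indices, ps, pe, cand):
                        wgt = 1.0
                    else:
                        wgt = explore_weight
                    total += wgt
                    cum[i] = total
                r = np.random.random() * total
                pick = np.searchsorted(cum, r, side="right")
                if pick >= deg:
                    pick = deg - 1
                nxt = indices[s + pick]
            out[w, step] = nxt
            prev = cur
            cur = nxt
    return out


@njit(cache=True)
def sgns_kernel(walks, window, dim, n_nodes, epochs, negatives, lr0,
                noise_prob, noise_alias, seed):
    """Skip-gram with negative sampling over a walk corpus.

    Returns ``(W, C, epoch_loss)`` where ``W`` are the input (node) vectors,
    ``C`` the output (context) vectors, and ``epoch_loss`` the mean negative
    log-likelihood per (center, sample) update in each epoch.  The learning
    rate decays linearly over the whole run with a floor of ``1e-4 * lr0``.
    """
    np.random.seed(seed)
    W = (np.random.random((n_nodes, dim)) - 0.5) / dim
    C = np.zeros((n_nodes, dim))
    n_walks, walk_len = walks.shape

    total_tokens = 0
    for w in range(n_walks):
        for i in range(walk_len):
            if walks[w, i] >= 0:
                total_tokens += 1
    total_tokens *= epochs
    if total_tokens == 0:
        return W, C, np.zeros(epochs)

    epoch_loss = np.zeros(epochs)
    grad = np.empty(dim)
    processed = 0
    for epoch in range(epochs):
        loss = 0.0
        n_updates = 0
        for w in range(n_walks):
            for i in range(walk_len):
                center = walks[w, i]
                if center < 0:
                    break
                lr = lr0 * (1.0 - processed / total_tokens)
                if lr < lr0 * 1e-4:
                    lr = lr0 * 1e-4
                processed += 1
                lo = i - window
                if lo < 0:
                    lo = 0
                hi = i + window + 1
                if hi > walk_len:
                    hi = walk_len
                for j in range(lo, hi):
                    context = walks[w, j]
                    if j == i or context < 0:
                        continue
                    for k in range(dim):
                        grad[k] = 0.0
                    for s in range(negatives + 1):
                        if s == 0:
                            target = context
                            label = 1.0
                        else:
                            target = _alias_draw(noise_prob, noise_alias)
                            label = 0.0
                        score = 0.0
                        for k in range(dim):
                            score += W[center, k] * C[target, k]
                        t = _sig_index(score)
                        sig = _SIG_TABLE[t]
                        if label > 0.5:
                            loss -= _LOG_SIG_TABLE[t]
                        else:
                            loss -= _LOG_NEG_TABLE[t]
                        g = (label - sig) * lr
                        for k in range(dim):
                            grad[k] += g * C[target, k]
                            C[target, k] += g * W[center, k]
                        n_updates += 1
                    for k in range(dim):
                        W[center, k] += grad[k]
        epoch_loss[epoch] = loss / max(n_updates, 1)
    return W, C, epoch_loss


@njit(cache=True)
def line_kernel(edge_u, edge_v, first_order, dim, n_nodes, total_samples,
                negatives, lr0, noise_prob, noise_alias, seed):
    """LINE embedding by per-sample stochastic updates on uniform edge draws.

    First order: a single vector table ``W``, objective ``log s(W_i . W_j)``
    with degree^(3/4) negative sampling over nodes.  Second order: vertex
    vectors ``W`` against context vectors ``C`` (``log s(C_j . W_i)``).
    Updates run for ``total_samples`` edge draws with linear learning-rate
    decay.  Edges are treated symmetrically: the source role alternates.
    """
    np.random.seed(seed)
    W = (np.random.random((n_nodes, dim)) - 0.5) / dim
    C = np.zeros((n_nodes, dim))
    m = edge_u.shape[0]
    grad = np.empty(dim)
    for it in range(total_samples):
        lr = lr0 * (1.0 - it / total_samples)
        if lr < lr0 * 1e-4:
            lr = lr0 * 1e-4
        e = np.random.randint(m)
        if it % 2 == 0:
            i, j = edge_u[e], edge_v[e]
        else:
            i, j = edge_v[e], edge_u[e]
        for k in range(dim):
            grad[k] = 0.0
        for s in range(negatives + 1):
            if s == 0:
                target = j
                label = 1.0
            else:
                target = _alias_draw(noise_prob, noise_alias)
                label = 0.0
            score = 0.0
            if first_order:
                for k in range(dim):
                    score += W[i, k] * W[target, k]
            else:
                for k in range(dim):
                    score += W[i, k] * C[target, k]
            sig = _SIG_TABLE[_sig_index(score)]
            g = (label - sig) * lr
            if first_order:
                for k in range(dim):
                    grad[k] += g * W[target, k]
                    W[target, k] += g * W[i, k]
            else:
                for k in range(dim):
                    grad[k] += g * C[target, k]
                    C[target, k] += g * W[i, k]
        for k in range(dim):
            W[i, k] += grad[k]
    return W, C
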