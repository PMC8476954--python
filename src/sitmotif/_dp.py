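"""Viterbi-style dynamic-programming kernels (numba-compiled).

Two decoders share the same switching-penalty model:

* :func:`viterbi_switch` — minimise ``sum_t cost[t, s_t] + beta * 1{s_t != s_{t-1}}``
  over plain state paths.
* :func:`viterbi_motif` — maximise the motif-aware score over an expanded
  node graph (one node per plain state plus one node per position of each
  motif), charging ``log(gamma)`` on measurements outside motif instances.

Tie-breaking is deterministic: stay with the previous state when equal,
otherwise take the lowest-indexed candidate.  In the expanded decoder the
plain-state nodes are ordered first, so with ``gamma = 1`` (no reward for
motif membership) ties resolve to exactly the plain decoder's path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e300


@njit(cache=False)
def viterbi_switch(cost, beta):
    """Exact minimiser of switching-penalised path cost.

    Parameters: ``cost`` (T, K) float64, ``beta`` >= 0 scalar.
    Returns states (T,) int64.
    """
    T, K = cost.shape
    states = np.empty(T, dtype=np.int64)
    if T == 0:
        return states
    dp = cost[0].copy()
    bp = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        best_prev = 0
        for j in range(1, K):
            if dp[j] < dp[best_prev]:
                best_prev = j
        new = np.empty(K)
        for k in range(K):
            stay = dp[k]
            switch = dp[best_prev] + beta
            if stay <= switch:
                new[k] = stay + cost[t, k]
                bp[t, k] = k
            else:
                new[k] = switch + cost[t, k]
                bp[t, k] = best_prev
        dp = new
    last = 0
    for j in range(1, K):
        if dp[j] < dp[last]:
            last = j
    states[T - 1] = last
    for t in range(T - 1, 0, -1):
        last = bp[t, last]
        states[t - 1] = last
    return states


@njit(cache=False)
def viterbi_motif(emis, node_state, node_motif, node_pos, node_final, n_ordinary,
                  beta, log_gamma):
    """Maximise the motif-aware objective over the expanded node graph.

    Parameters
    ----------
    emis : (T, K) float64
        Per-measurement state log-likelihoods.
    node_state, node_motif, node_pos : (n_nodes,) int64
        Underlying state id (0-based), owning motif index (-1 for ordinary
        nodes) and position within the motif for each node.  Ordinary nodes
        occupy indices ``0 .. n_ordinary-1`` in state order.
    node_final : (n_nodes,) bool
        True for ordinary nodes and for the last position of each motif —
        the nodes from which a free transition (to any ordinary node or any
        motif start) is allowed.
    beta, log_gamma : float
        Switching penalty; per-measurement reward withheld outside motifs
        (``log_gamma <= 0``).

    Returns the node path (T,) int64; the caller derives states and motif
    instances from it.
    """
    T, K = emis.shape
    n_nodes = node_state.shape[0]
    path = np.empty(T, dtype=np.int64)
    if T == 0:
        return path
    dp = np.full(n_nodes, NEG_INF)
    bp = np.zeros((T, n_nodes), dtype=np.int64)
    # start: ordinary nodes, or the first position of a motif
    for v in range(n_nodes):
        s = node_state[v]
        if node_motif[v] == -1:
            dp[v] = emis[0, s] + log_gamma
        elif node_pos[v] == 0:
            dp[v] = emis[0, s]
    for t in range(1, T):
        # best "free" predecessor overall and per underlying state
        free_best = NEG_INF
        free_arg = -1
        state_best = np.full(K, NEG_INF)
        state_arg = np.full(K, -1, dtype=np.int64)
        for v in range(n_nodes):
            if node_final[v] and dp[v] > NEG_INF:
                if dp[v] > free_best:
                    free_best = dp[v]
                    free_arg = v
                s = node_state[v]
                if dp[v] > state_best[s]:
                    state_best[s] = dp[v]
                    state_arg[s] = v
        new = np.full(n_nodes, NEG_INF)
        for v in range(n_nodes):
            s = node_state[v]
            # free entry: from a same-state final node (no penalty) or any
            # final node (penalty beta); prefer the no-switch option on ties
            entry = NEG_INF
            entry_arg = -1
            if state_arg[s] >= 0:
                entry = state_best[s]
                entry_arg = state_arg[s]
            if free_arg >= 0 and free_best - beta > entry:
                entry = free_best - beta
                entry_arg = free_arg
            if node_motif[v] == -1:
                if entry_arg >= 0:
                    new[v] = entry + emis[t, s] + log_gamma
                    bp[t, v] = entry_arg
            elif node_pos[v] == 0:
                # enter the motif, or keep extending its first state run
                best = entry
                best_arg = entry_arg
                if dp[v] > best:
                    best = dp[v]
                    best_arg = v
                if best_arg >= 0:
                    new[v] = best + emis[t, s]
                    bp[t, v] = best_arg
            else:
                # stay on this motif position, or advance from the previous
                # one (adjacent motif states always differ, so beta applies)
                best = dp[v]
                best_arg = v
                adv = dp[v - 1] - beta
                if adv > best:
                    best = adv
                    best_arg = v - 1
                if best > NEG_INF and best_arg >= 0:
                    new[v] = best + emis[t, s]
                    bp[t, v] = best_arg
        dp = new
    # terminate on an ordinary node or a completed motif
    last = -1
    best = NEG_INF
    for v in range(n_nodes):
        if node_final[v] and dp[v] > best:
            best = dp[v]
            last = v
    if last < 0:
        # no feasible path (can happen when gamma == 0 forbids every
        # non-motif assignment); the caller raises a config error
        path[:] = -1
        return path
    path[T - 1] = last
    for t in range(T - 1, 0, -1):
        last = bp[t, last]
        path[t - 1] = last
    return path
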