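"""Motif-aware state assignment (MASA) over TICC states.

A *motif* is an ordered sequence of states in the run-length-compressed
state sequence (neighbouring repeats of a state merge into one run): it must
contain more than two states, adjacent entries must differ, and it must
recur more than ``L`` times with non-overlapping instances.  Instances may
stretch each motif state over a variable number of measurements.

Discovery and assignment are iterated EM-style on the objective

    sum_i [ log P(X_i | S_i) - beta 1{S_i != S_{i-1}} + log(gamma) 1{S_i not in a motif} ]
        + Psi(M) - R(Theta)

where ``gamma`` in [0, 1] is the cost of leaving a measurement outside every
motif instance (lower gamma = harsher), ``Psi`` scores motif strength and
``R`` reuses the l1 sparsity penalty of the state model.  The state-path part
is decoded exactly by dynamic programming over an expanded graph with one
node per position of each candidate motif.

``Psi`` here is frequency x length x null-model log-odds:
``Psi(m, q) = |q| * sum_i -log f(m_i)`` with ``f`` the empirical compressed
state frequencies — motifs score higher the more often they recur and the
less likely they are under independent state draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._dp import viterbi_motif
from .exceptions import ConfigError
from .ticc import TICCModel, ToeplitzPrecision, assign_states, emission_matrix, \
    fit_toeplitz_precision

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# motif types


@dataclass(frozen=True)
class Motif:
    """An ordered state-id sequence; > 2 entries, adjacent entries differ."""

    states: tuple

    def __post_init__(self) -> None:
        states = tuple(int(s) for s in self.states)
        object.__setattr__(self, "states", states)
        if len(states) <= 2:
            raise ConfigError(f"motif must contain at least three states, got {states}")
        if any(a == b for a, b in zip(states, states[1:])):
            raise ConfigError(f"adjacent motif states must differ: {states}")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)


@dataclass
class MASAConfig:
    """``gamma``: non-motif cost in [0, 1]; ``L``: minimum recurrences;
    ``beta`` is shared with the segmentation step."""

    gamma: float = 0.9
    L: int = 5
    beta: float = 50.0
    max_len: int = 6
    top_k: int = 10
    max_iter: int = 5
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigError("gamma must lie in [0, 1]")
        if self.L < 1:
            raise ConfigError("L must be >= 1")


@dataclass
class MASAModel:
    """Fitted motif model: states, per-motif scores and instances.

    ``motifs`` is a list of dicts (motif, score, count, instances per
    segment) sorted by score; the first entry is the "common motif".
    ``assignments`` mirrors the input segmentation (list of per-day state
    arrays, or a single array when a single series was fitted).
    """

    thetas: list
    assignments: list
    motifs: list
    objective_trace: list
    config: MASAConfig

    @property
    def common_motif(self):
        return self.motifs[0]["motif"] if self.motifs else None


# ---------------------------------------------------------------------------
# run-length compression


def compress_states(S) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a state sequence; returns (states, run lengths)."""
    S = np.asarray(S)
    if len(S) == 0:
        return S.copy(), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(S)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(S)]))
    return S[starts], (ends - starts).astype(np.int64)


def decompress_states(states, lengths) -> np.ndarray:
    """Inverse of :func:`compress_states`."""
    return np.repeat(np.asarray(states), np.asarray(lengths))


# ---------------------------------------------------------------------------
# candidate enumeration and scoring


def _greedy_count(comp: np.ndarray, pattern: tuple) -> int:
    """Non-overlapping occurrences of ``pattern`` in ``comp``, greedy left-to-right."""
    l = len(pattern)
    comp = np.asarray(comp)
    if len(comp) < l:
        return 0
    win = np.lib.stride_tricks.sliding_window_view(comp, l)
    hits = np.flatnonzero((win == np.asarray(pattern)).all(axis=1))
    count, next_free = 0, 0
    for i in hits:
        if i >= next_free:
            count += 1
            next_free = i + l
    return count


def enumerate_candidates(compressed, L: int, max_len: int = 6) -> list:
    """All motifs recurring more than L times (non-overlapping, greedy).

    ``compressed`` is one run-length-compressed sequence or a list of them
    (multi-day pooling: candidates are drawn and counted across all
    sequences, occurrences never span a boundary).  Returns
    ``[(Motif, count), ...]`` sorted by count then by motif for determinism.
    """
    if L < 1:
        raise ConfigError("L must be >= 1")
    seqs = compressed if isinstance(compressed, (list, tuple)) else [compressed]
    seqs = [np.asarray(s) for s in seqs]
    patterns = set()
    for s in seqs:
        for l in range(3, max_len + 1):
            for i in range(len(s) - l + 1):
                patterns.add(tuple(int(v) for v in s[i:i + l]))
    counts = {}
    for pat in patterns:
        count = sum(_greedy_count(s, pat) for s in seqs)
        if count > L:
            counts[pat] = count
    kept = _closed_patterns(counts)
    out = [(Motif(pat), c) for pat, c in kept.items()]
    out.sort(key=lambda mc: (-mc[1], mc[0].states))
    return out


def _closed_patterns(counts: dict) -> dict:
    """Closed-pattern pruning.

    A candidate is dropped when a strict contiguous sub-motif recurs more
    often (the extension is incidental context), and a sub-motif is dropped
    when a super-pattern recurs exactly as often (the sub never occurs on
    its own).  Genuinely longer motifs therefore survive, incidental
    extensions of a frequent core do not.
    """

    def subpatterns(pat):
        for l in range(3, len(pat)):
            for i in range(len(pat) - l + 1):
                yield pat[i:i + l]

    kept = {}
    for pat, c in counts.items():
        subs = [s for s in subpatterns(pat) if s in counts]
        if any(counts[s] > c for s in subs):
            continue
        kept[pat] = c
    absorbed = set()
    for pat in kept:
        for s in subpatterns(pat):
            if s in kept and kept[s] == kept[pat]:
                absorbed.add(s)
    return {p: c for p, c in kept.items() if p not in absorbed}


def state_frequencies(compressed, n_states: int) -> np.ndarray:
    """Empirical state frequencies of the compressed sequence(s)."""
    seqs = compressed if isinstance(compressed, (list, tuple)) else [compressed]
    counts = np.zeros(n_states)
    for s in seqs:
        counts += np.bincount(np.asarray(s, dtype=np.int64), minlength=n_states)
    total = counts.sum()
    return counts / total if total else np.full(n_states, 1.0 / n_states)


def score_motif(motif: Motif, instances, state_freqs=None) -> float:
    """Motif strength Psi: instance count x summed state surprisal.

    ``instances`` may be a count or a list of instances.  With no frequency
    table the null model is uniform over the states present in the motif.
    """
    n_inst = instances if np.isscalar(instances) else len(instances)
    if n_inst == 0:
        return 0.0
    if state_freqs is None:
        k = len(set(motif.states))
        surprisal = len(motif) * float(-np.log(1.0 / k))
    else:
        f = np.asarray(state_freqs, dtype=float)
        f = np.clip(f, 1e-12, None)
        surprisal = float(np.sum(-np.log(f[list(motif.states)])))
    return float(n_inst) * surprisal


# ---------------------------------------------------------------------------
# motif-aware decoding


def _build_nodes(K: int, motifs: list):
    node_state, node_motif, node_pos, node_final = [], [], [], []
    for k in range(K):
        node_state.append(k)
        node_motif.append(-1)
        node_pos.append(0)
        node_final.append(True)
    for r, m in enumerate(motifs):
        for p, s in enumerate(m.states):
            node_state.append(s)
            node_motif.append(r)
            node_pos.append(p)
            node_final.append(p == len(m) - 1)
    return (np.asarray(node_state, dtype=np.int64),
            np.asarray(node_motif, dtype=np.int64),
            np.asarray(node_pos, dtype=np.int64),
            np.asarray(node_final, dtype=bool))


def assign_with_motifs(windows, thetas, motifs, beta: float, gamma: float):
    """Exact motif-aware decoding of one window sequence.

    Returns ``(S, instances)`` where ``instances`` maps motif index to a list
    of ``(start, end)`` half-open window-index ranges.  With ``gamma = 1``
    the decoded states coincide with plain :func:`sitmotif.ticc.assign_states`
    (no reward for motif membership; ties resolve to ordinary nodes).
    """
    if thetas is not None:
        emis = emission_matrix(np.asarray(windows, dtype=float), thetas)
    else:
        emis = np.asarray(windows, dtype=float)
    K = emis.shape[1]
    motifs = list(motifs)
    for m in motifs:
        if any(s < 0 or s >= K for s in m.states):
            raise ConfigError(f"motif {m.states} references an unknown state id")
    if emis.shape[0] == 0:
        return np.empty(0, dtype=np.int64), {r: [] for r in range(len(motifs))}
    log_gamma = -np.inf if gamma == 0.0 else float(np.log(gamma))
    if not np.isfinite(log_gamma):
        log_gamma = -1e30
    node_state, node_motif, node_pos, node_final = _build_nodes(K, motifs)
    path = viterbi_motif(np.ascontiguousarray(emis, dtype=np.float64),
                         node_state, node_motif, node_pos, node_final,
                         K, float(beta), log_gamma)
    if path[-1] < 0 or (gamma == 0.0 and np.any(node_motif[path] == -1)):
        raise ConfigError(
            "no feasible assignment: gamma = 0 forbids every non-motif "
            "measurement and the motifs cannot tile the series; use gamma > 0")
    S = node_state[path]
    instances: dict = {r: [] for r in range(len(motifs))}
    in_motif = node_motif[path]
    t = 0
    T = len(path)
    while t < T:
        r = in_motif[t]
        if r < 0:
            t += 1
            continue
        start = t
        while t < T and in_motif[t] == r and not (t > start and node_pos[path[t]] == 0
                                                  and node_pos[path[t - 1]] != 0):
            t += 1
        instances[int(r)].append((int(start), int(t)))
    return S, instances


# ---------------------------------------------------------------------------
# EM fit


def fit_masa(windows, ticc_model: TICCModel, config: MASAConfig) -> MASAModel:
    """Iterate candidate discovery, motif-aware decoding and state refits.

    ``windows`` is one stacked array or a list of per-day arrays (motifs are
    pooled across days, decoding is per day).  Iterations are accepted only
    while the objective improves, so the trace is non-decreasing; if no
    candidate satisfies the constraints the model has an empty motif set.
    """
    single = not isinstance(windows, (list, tuple))
    segs = [np.atleast_2d(np.asarray(windows, dtype=float))] if single else \
        [np.atleast_2d(np.asarray(s, dtype=float)) for s in windows]
    thetas = list(ticc_model.thetas)
    K = len(thetas)
    lam = ticc_model.config.lam
    w, n = ticc_model.config.w, thetas[0].n

    S_list = [assign_states(seg, thetas, config.beta) for seg in segs]
    best = None
    trace = []
    for it in range(config.max_iter):
        comp = [compress_states(S)[0] for S in S_list]
        cands = enumerate_candidates(comp, config.L, config.max_len)
        freqs = state_frequencies(comp, K)
        scored = sorted(((score_motif(m, c, freqs), m, c) for m, c in cands),
                        key=lambda x: (-x[0], x[1].states))
        motifs = [m for _, m, _ in scored[: config.top_k]]
        if not motifs:
            logger.info("fit_masa: no candidate motif satisfies the constraints")
            obj = _masa_objective(segs, thetas, S_list,
                                  [{} for _ in segs], [], config, lam)
            if best is None:
                best = (thetas, S_list, [], obj)
                trace.append(obj)
            break
        new_S, new_inst = [], []
        for seg in segs:
            S, inst = assign_with_motifs(seg, thetas, motifs, config.beta, config.gamma)
            new_S.append(S)
            new_inst.append(inst)
        new_thetas = _refit_thetas(segs, new_S, K, lam, w, n, thetas)
        obj = _masa_objective(segs, new_thetas, new_S, new_inst, motifs, config, lam)
        if best is not None and obj <= best[3] + config.tol:
            break
        motif_records = _motif_records(motifs, new_inst, comp, freqs, config)
        best = (new_thetas, new_S, motif_records, obj)
        trace.append(obj)
        thetas, S_list = new_thetas, new_S
    if best is None:  # max_iter == 0
        best = (thetas, S_list, [], np.nan)
    thetas, S_list, motif_records, _ = best
    return MASAModel(thetas=thetas,
                     assignments=S_list[0] if single else S_list,
                     motifs=motif_records, objective_trace=trace, config=config)


def _refit_thetas(segs, S_list, K, lam, w, n, old):
    out = []
    for k in range(K):
        members = np.vstack([seg[S == k] for seg, S in zip(segs, S_list)
                             if np.any(S == k)]) if any(np.any(S == k) for S in S_list) \
            else None
        if members is None or len(members) == 0:
            out.append(old[k])
            continue
        out.append(fit_toeplitz_precision(members, lam, w, n))
    return out


def _masa_objective(segs, thetas, S_list, inst_list, motifs, config, lam) -> float:
    """Eq-style score: data ll - beta switches + log(gamma) non-motif + Psi - R."""
    log_gamma = -1e30 if config.gamma == 0 else float(np.log(config.gamma))
    total = 0.0
    for seg, S, inst in zip(segs, S_list, inst_list):
        emis = emission_matrix(seg, thetas)
        total += float(emis[np.arange(len(seg)), S].sum())
        total -= config.beta * int(np.count_nonzero(np.diff(S)))
        covered = np.zeros(len(seg), dtype=bool)
        for spans in inst.values():
            for a, b in spans:
                covered[a:b] = True
        total += log_gamma * int(np.count_nonzero(~covered))
    comp = [compress_states(S)[0] for S in S_list]
    freqs = state_frequencies(comp, len(thetas))
    for r, m in enumerate(motifs):
        n_inst = sum(len(inst[r]) for inst in inst_list)
        total += score_motif(m, n_inst, freqs)
    for th in thetas:
        total -= lam * (np.abs(th.theta).sum() - np.abs(np.diag(th.theta)).sum())
    return total


def _motif_records(motifs, inst_list, comp, freqs, config) -> list:
    records = []
    for r, m in enumerate(motifs):
        spans = [inst[r] for inst in inst_list]
        n_inst = sum(len(sp) for sp in spans)
        records.append({
            "motif": m,
            "score": score_motif(m, n_inst, freqs),
            "count": n_inst,
            "instances": spans,
            "psi_form": "count * sum(-log f(state))",
        })
    records.sort(key=lambda rec: (-rec["score"], rec["motif"].states))
    return records


def motif_occurrence_rate(instances, sitting_hours: float) -> float:
    """Instances per 30 sitting minutes: ``count / (hours * 2)``.

    Returns NaN (logged) for zero sitting time.
    """
    n = instances if np.isscalar(instances) else len(instances)
    if sitting_hours <= 0:
        logger.warning("motif_occurrence_rate: zero sitting time, rate undefined")
        return float("nan")
    return float(n) / (sitting_hours * 2.0)
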