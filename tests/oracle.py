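"""Brute-force explicit-state Viterbi used as an independent oracle.

Materializes every NR/R/I/D/J state of the model's explicit state space and
runs the textbook dynamic program over a dense per-state table, with silent
deletion states relaxed in chain order between positions.  No J-chain
shortcut, no windowing: this is deliberately the slow, obviously-correct
formulation the optimized decoder must agree with.
"""

from __future__ import annotations

import math

import numpy as np

from tandemhmm.model import StateSpace, background_prob, emission_log_ratio_table

NEG_INF = -np.inf


def explicit_viterbi(seq, space: StateSpace, relative: bool = True):
    """Return (best score, per-position State labels) for an encoded sequence.

    With ``relative=False`` raw emission probabilities are used instead of
    emission/background ratios (the basic form of the recurrence): every
    state's log emission gains the log background frequency of the emitted
    letter.
    """
    params = space.params
    seq = np.asarray(seq)
    n = len(seq)
    states = space.states
    m = len(states)
    table = emission_log_ratio_table(params)
    boundary = math.log(1.0 - params.match_prob)
    log_bg = np.array([
        math.log(background_prob(i, params))
        for i in range(params.alphabet.size + 1)
    ])

    def emission(state, t):
        if state.kind in ("NR", "I"):
            e = 0.0
        elif t - state.look_back < 0:
            e = boundary
        else:
            e = table[seq[t], seq[t - state.look_back]]
        if not relative:
            e += log_bg[seq[t]]
        return e

    silent = [i for i, s in enumerate(states) if s.kind == "D"]
    emitting = [i for i, s in enumerate(states) if s.kind != "D"]
    in_edges: list[list[tuple[int, float]]] = [[] for _ in range(m)]
    for (u, v), logp in space.transitions.items():
        in_edges[v].append((u, logp))
    nr = 0

    V = np.full((m, n), NEG_INF)
    ptr = np.full((m, n), -1, dtype=np.int64)
    Sval = np.full((m, n), NEG_INF)  # silent-state values at the boundary after t
    Sptr = np.full((m, n), -1, dtype=np.int64)

    for t in range(n):
        for v in emitting:
            best, arg = NEG_INF, -1
            if t == 0:
                logp = space.transitions.get((nr, v))
                if logp is not None:
                    best, arg = logp, nr
            else:
                for u, logp in in_edges[v]:
                    w = V[u, t - 1] if states[u].kind != "D" else Sval[u, t - 1]
                    cand = w + logp
                    if cand > best:
                        best, arg = cand, u
            if best > NEG_INF:
                V[v, t] = best + emission(states[v], t)
                ptr[v, t] = arg
        # silent deletion chains hang off the values just computed at t;
        # enumeration order follows the chains, so a single pass relaxes them
        for v in silent:
            best, arg = NEG_INF, -1
            for u, logp in in_edges[v]:
                w = V[u, t] if states[u].kind != "D" else Sval[u, t]
                cand = w + logp
                if cand > best:
                    best, arg = cand, u
            Sval[v, t] = best
            Sptr[v, t] = arg

    # terminal argmax over emitting states; enumeration order = tie-break order
    end = min(emitting, key=lambda v: (-V[v, n - 1], v))
    score = V[end, n - 1]

    labels = []
    v, t = end, n - 1
    while t >= 0:
        labels.append(states[v])
        u = int(ptr[v, t])
        while u >= 0 and states[u].kind == "D":
            u = int(Sptr[u, t - 1])
        v, t = u, t - 1
    labels.reverse()
    return float(score), labels
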