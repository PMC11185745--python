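"""Viterbi decoding of the repeat HMM, windowed for long sequences.

Decoding uses relative emission likelihoods: every emission probability is
divided by the background frequency of the emitted letter, which makes
repeat scores composition-aware (a run of common letters is less surprising
than a run of rare ones).  All arithmetic is in natural-log space.

The dynamic program never materializes individual J-states.  Because a
J-chain, once entered, is a forced walk of exactly ``p`` context-shifted
emissions returning to R(p), an entire indel excursion (I-run or silent
D-run plus its J-chain) collapses into a single "macro" transition from
R(p) at an earlier position to R(p) at the current one, evaluated in O(1)
with prefix sums of the shifted emission scores.  This is observationally
equivalent to running Viterbi over the explicit state space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit

from .model import (
    ConfigurationError,
    ModelParams,
    StateSpace,
    emission_log_ratio_table,
    gamma_vector,
)

__all__ = [
    "DecodedPath",
    "WindowPlan",
    "viterbi_decode",
    "plan_windows",
    "decode_windowed",
    "estimate_memory",
]

# label kind codes
NR, R, I, J = 0, 1, 2, 3

NEG_INF = -np.inf
CELL_BYTES = 8
DEFAULT_MEMORY_BUDGET = 256 * 1024 * 1024  # per-thread window sizing budget


@dataclass
class DecodedPath:
    """Per-position most-likely state labels plus a running log-score.

    ``kind`` holds 0/1/2/3 for NR/R/I/J; ``period`` and ``look_back`` are 0
    for context-blind labels.  Deleted letters occupy no positions; a
    deletion run of length j is recorded as ``del_before[t] = j`` on the
    first J-position that follows it.  ``cumulative_log`` is the Viterbi
    log-score of the winning path prefix ending at each position.
    """

    kind: np.ndarray
    period: np.ndarray
    look_back: np.ndarray
    chain_pos: np.ndarray
    del_before: np.ndarray
    cumulative_log: np.ndarray
    params: ModelParams
    sequence: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.kind)

    def contributions(self) -> np.ndarray:
        """Per-position log T + log(E/E0) terms recomputed from the labels
        (cached after the first call)."""
        if getattr(self, "_contribs", None) is None:
            self._contribs = path_contributions(self, self.sequence, self.params)
        return self._contribs


@dataclass(frozen=True)
class WindowPlan:
    window_size: int
    overlap: int
    windows: tuple[tuple[int, int], ...]


@lru_cache(maxsize=8)
def _transition_arrays(params: ModelParams):
    """Precompute the log-cost vectors used by the DP and by rescoring."""
    k, i, d = params.k, params.max_insert, params.max_delete
    rho = params.indel_extend
    io = params.indel_open
    gam = gamma_vector(params)
    log_half_open = math.log(io / 2.0) if io > 0 else NEG_INF
    log_rho = math.log(rho) if rho > 0 else NEG_INF
    log_exit_run = math.log1p(-rho) if rho < 1 else NEG_INF

    lt_enter = np.full(k + 1, NEG_INF)
    lt_self = np.full(k + 1, NEG_INF)
    d_caps = np.zeros(k + 1, dtype=np.int64)
    for p in range(1, k + 1):
        if params.nu_in > 0:
            lt_enter[p] = math.log(params.nu_in * gam[p])
        d_caps[p] = params.max_delete_for(p)
        open_mass = (io / 2.0 if i >= 1 else 0.0) + (io / 2.0 if d_caps[p] >= 1 else 0.0)
        stay = 1.0 - params.nu_out - open_mass
        lt_self[p] = math.log(stay) if stay > 0 else NEG_INF

    ci = np.full(i + 1, NEG_INF)  # full I-run cost incl. exit into J-chain
    ci_partial = np.full(i + 1, NEG_INF)  # I-run cost without the exit term
    for a in range(1, i + 1):
        ci_partial[a] = log_half_open + (a - 1) * log_rho
        ci[a] = ci_partial[a] + (log_exit_run if a < i else 0.0)

    cd = np.full((k + 1, d + 1), NEG_INF)
    for p in range(1, k + 1):
        for j in range(1, d_caps[p] + 1):
            cd[p, j] = log_half_open + (j - 1) * log_rho
            if j < d_caps[p]:
                cd[p, j] += log_exit_run

    log_stay_nr = math.log1p(-params.nu_in)
    log_exit = math.log(params.nu_out) if params.nu_out > 0 else NEG_INF
    return lt_enter, lt_self, ci, ci_partial, cd, d_caps, log_stay_nr, log_exit


def _emission_rows(seq: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Log relative-emission rows eR[q, t] for look-backs q = 1..k+i, plus
    their prefix sums CR[q, t] = sum of eR[q, :t].

    Positions with t - q < 0 have no look-back letter inside the window and
    are scored as a mismatch against an unknown (ambiguous) context.
    """
    table = emission_log_ratio_table(params)
    qmax = params.k + params.max_insert
    L = len(seq)
    boundary = math.log(1.0 - params.match_prob)
    eR = np.empty((qmax + 1, L), dtype=np.float64)
    eR[0] = 0.0
    for q in range(1, qmax + 1):
        if q < L:
            eR[q, q:] = table[seq[q:], seq[:-q]]
        eR[q, : min(q, L)] = boundary
    CR = np.zeros((qmax + 1, L + 1), dtype=np.float64)
    np.cumsum(eR, axis=1, out=CR[:, 1:])
    return eR, CR


@njit(cache=True, nogil=True)
def _viterbi_core(eR, CR, lt_enter, lt_self, ci, cd, d_caps, log_stay_nr, log_exit, k, i_max):
    L = eR.shape[1]
    VN = np.full(L, NEG_INF)
    VR = np.full((k + 1, L), NEG_INF)
    BTN = np.zeros(L, dtype=np.int32)  # 0 = from NR, p = from R(p)
    BTR = np.zeros((k + 1, L), dtype=np.int16)  # 0 self, 1 NR, 1+a ins, 1+i+j del
    for t in range(L):
        prev_vn = VN[t - 1] if t > 0 else 0.0
        # non-repetitive state: ties prefer staying in NR
        best = prev_vn + log_stay_nr
        code = 0
        if t > 0:
            for p in range(1, k + 1):
                cand = VR[p, t - 1] + log_exit
                if cand > best:
                    best = cand
                    code = p
        VN[t] = best
        BTN[t] = code
        for p in range(1, k + 1):
            # ties prefer entering fresh from NR, then extending the repeat,
            # then indel macros (insertions before deletions, short runs first)
            best = prev_vn + lt_enter[p]
            code = 1
            if t > 0:
                cand = VR[p, t - 1] + lt_self[p]
                if cand > best:
                    best = cand
                    code = 0
            for a in range(1, i_max + 1):
                s = t - 1 - a - p
                if s < 0:
                    break
                cand = VR[p, s] + ci[a] + (CR[p + a, t] - CR[p + a, t - p])
                if cand > best:
                    best = cand
                    code = 1 + a
            for j in range(1, d_caps[p] + 1):
                s = t - 1 - p
                if s < 0:
                    break
                cand = VR[p, s] + cd[p, j] + (CR[p - j, t] - CR[p - j, t - p])
                if cand > best:
                    best = cand
                    code = 1 + i_max + j
            VR[p, t] = best + eR[p, t]
            BTR[p, t] = code
    return VN, VR, BTN, BTR


def _terminal_state(VN, VR, CR, params, ci, ci_partial, cd, d_caps):
    """Best state at the final position, including paths that end inside an
    I-run or J-chain.  Ties prefer NR, then smaller period, then non-indel."""
    L = VN.shape[0]
    T = L - 1
    k, i = params.k, params.max_insert
    best = VN[T]
    final = (NR, 0, 0, 0)
    for p in range(1, k + 1):
        if VR[p, T] > best:
            best = VR[p, T]
            final = (R, p, 0, 0)
        for a in range(1, i + 1):
            s = T - a
            if s >= 0 and np.isfinite(VR[p, s]):
                cand = VR[p, s] + ci_partial[a]
                if cand > best:
                    best = cand
                    final = (I, p, a, 0)
            for c in range(1, p + 1):
                s = T - a - c
                if s < 0:
                    break
                cand = VR[p, s] + ci[a] + (CR[p + a, T + 1] - CR[p + a, T + 1 - c])
                if cand > best:
                    best = cand
                    final = (J, p, a, c)
        for j in range(1, d_caps[p] + 1):
            for c in range(1, p + 1):
                s = T - c
                if s < 0:
                    break
                cand = VR[p, s] + cd[p, j] + (CR[p - j, T + 1] - CR[p - j, T + 1 - c])
                if cand > best:
                    best = cand
                    final = (J, p, -j, c)
    return best, final


def viterbi_decode(
    sequence,
    params: ModelParams | None = None,
    state_space: StateSpace | None = None,
) -> DecodedPath:
    """Most probable state path for a sequence under the repeat model.

    ``sequence`` may be a string over the model alphabet (plus ambiguity) or
    an already-encoded int array.  Boundary condition: decoding begins in the
    non-repetitive state with probability 1.
    """
    if params is None:
        if state_space is None:
            raise ValueError("provide params or a state space")
        params = state_space.params
    if isinstance(sequence, str):
        seq = params.alphabet.encode(sequence)
    else:
        seq = np.asarray(sequence, dtype=np.int8)
    L = len(seq)
    if L == 0:
        empty = np.zeros(0, dtype=np.int16)
        return DecodedPath(
            empty.astype(np.int8), empty, empty, empty, empty,
            np.zeros(0), params, seq,
        )

    arrays = _transition_arrays(params)
    lt_enter, lt_self, ci, ci_partial, cd, d_caps, log_stay_nr, log_exit = arrays
    eR, CR = _emission_rows(seq, params)
    VN, VR, BTN, BTR = _viterbi_core(
        eR, CR, lt_enter, lt_self, ci, cd, d_caps,
        log_stay_nr, log_exit, params.k, params.max_insert,
    )
    best_score, final = _terminal_state(VN, VR, CR, params, ci, ci_partial, cd, d_caps)

    path = _backtrace(seq, params, eR, VN, VR, BTN, BTR, ci, ci_partial, cd, final)
    if not math.isclose(path.cumulative_log[-1], best_score, rel_tol=0, abs_tol=1e-6):
        raise AssertionError("backtrace score disagrees with DP optimum")
    return path


def _backtrace(seq, params, eR, VN, VR, BTN, BTR, ci, ci_partial, cd, final):
    L = len(seq)
    i_max = params.max_insert
    kind = np.zeros(L, dtype=np.int8)
    period = np.zeros(L, dtype=np.int16)
    look_back = np.zeros(L, dtype=np.int16)
    chain_pos = np.zeros(L, dtype=np.int16)
    del_before = np.zeros(L, dtype=np.int16)
    cum = np.zeros(L, dtype=np.float64)

    def fill_chain(t_end, p, o, c, base_val):
        """Label J_1..J_c at positions t_end-c+1..t_end; base_val is the DP
        value just before J_1 emits (R value at entry + run cost)."""
        q = p + o
        v = base_val
        for m in range(1, c + 1):
            t = t_end - c + m
            v += eR[q, t]
            kind[t] = J
            period[t] = p
            look_back[t] = q
            chain_pos[t] = m
            cum[t] = v
        if o < 0:
            del_before[t_end - c + 1] = -o

    def fill_insert_run(t_end, p, a, r_val):
        """Label I_1..I_a at positions t_end-a+1..t_end."""
        for m in range(1, a + 1):
            t = t_end - a + m
            kind[t] = I
            period[t] = p
            chain_pos[t] = m
            cum[t] = r_val + ci_partial[m]

    # expand a terminal partial excursion, then walk the main backpointers
    fkind, fp, frun, fc = final
    if fkind == NR:
        t, at_nr = L - 1, True
    elif fkind == R:
        t, at_nr, cur_p = L - 1, False, fp
    elif fkind == I:
        s = L - 1 - frun
        fill_insert_run(L - 1, fp, frun, VR[fp, s])
        t, at_nr, cur_p = s, False, fp
    else:  # mid J-chain
        c = fc
        if frun > 0:
            s = L - 1 - frun - c
            fill_chain(L - 1, fp, frun, c, VR[fp, s] + ci[frun])
            fill_insert_run(L - 1 - c, fp, frun, VR[fp, s])
        else:
            s = L - 1 - c
            fill_chain(L - 1, fp, frun, c, VR[fp, s] + cd[fp, -frun])
        t, at_nr, cur_p = s, False, fp

    while t >= 0:
        if at_nr:
            kind[t] = NR
            cum[t] = VN[t]
            src = BTN[t]
            if src != 0:
                at_nr, cur_p = False, int(src)
            t -= 1
            continue
        p = cur_p
        kind[t] = R
        period[t] = p
        look_back[t] = p
        cum[t] = VR[p, t]
        code = int(BTR[p, t])
        if code == 1:  # entered from NR
            at_nr = True
            t -= 1
        elif code == 0:  # self transition
            t -= 1
        elif code <= 1 + i_max:  # insertion macro
            a = code - 1
            s = t - 1 - a - p
            fill_chain(t - 1, p, a, p, VR[p, s] + ci[a])
            fill_insert_run(t - 1 - p, p, a, VR[p, s])
            t = s
        else:  # deletion macro
            j = code - 1 - i_max
            s = t - 1 - p
            fill_chain(t - 1, p, -j, p, VR[p, s] + cd[p, j])
            t = s

    return DecodedPath(kind, period, look_back, chain_pos, del_before, cum, params, seq)


def path_contributions(path: DecodedPath, seq: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-position log T + log(E/E0) along a label sequence.

    Independent of the DP internals: reads only the labels.  Transitions that
    are impossible under the model topology (they can arise at window-stitch
    points) are scored as a fresh entry from/exit to the non-repetitive
    state.
    """
    lt_enter, lt_self, ci, ci_partial, cd, d_caps, log_stay_nr, log_exit = (
        _transition_arrays(params)
    )
    table = emission_log_ratio_table(params)
    rho = params.indel_extend
    log_rho = math.log(rho) if rho > 0 else NEG_INF
    log_exit_run = math.log1p(-rho) if rho < 1 else NEG_INF
    log_half_open = math.log(params.indel_open / 2.0) if params.indel_open > 0 else NEG_INF
    boundary = math.log(1.0 - params.match_prob)
    L = len(path)
    if L == 0:
        return np.zeros(0)

    kd = path.kind.astype(np.int64)
    p = path.period.astype(np.int64)
    c = path.chain_pos.astype(np.int64)
    q = path.look_back.astype(np.int64)
    jdel = path.del_before.astype(np.int64)
    # previous-position labels; the virtual predecessor of position 0 is NR
    pk = np.concatenate(([NR], kd[:-1]))
    pp = np.concatenate(([0], p[:-1]))
    pc = np.concatenate(([0], c[:-1]))
    plb = np.concatenate(([0], q[:-1]))

    # default: any topologically impossible pair (stitch artifact) is scored
    # as a fresh entry into the current state's repeat
    trans = lt_enter[p]
    is_nr = kd == NR
    trans[is_nr] = np.where(pk[is_nr] == NR, log_stay_nr, log_exit)
    m = (kd == R) & (pk == R) & (pp == p)
    trans[m] = lt_self[p[m]]
    m = (kd == R) & (pk == J) & (pp == p) & (pc == p)
    trans[m] = 0.0  # J-chain completion
    m = (kd == I) & (c == 1) & (pk == R) & (pp == p)
    trans[m] = log_half_open
    m = (kd == I) & (c > 1) & (pk == I) & (pp == p) & (pc == c - 1)
    trans[m] = log_rho
    m = (kd == J) & (c == 1) & (jdel > 0) & (pk == R) & (pp == p)
    trans[m] = cd[p[m], jdel[m]]
    m = (kd == J) & (c == 1) & (jdel == 0) & (pk == I) & (pp == p)
    trans[m] = np.where(pc[m] < params.max_insert, log_exit_run, 0.0)
    m = (kd == J) & (c > 1) & (pk == J) & (pp == p) & (pc == c - 1) & (plb == q)
    trans[m] = 0.0

    emit = np.zeros(L)
    ctx = (kd == R) | (kd == J)
    src = np.arange(L) - q
    valid = ctx & (src >= 0)
    emit[ctx] = boundary
    emit[valid] = table[seq[valid], seq[src[valid]]]
    return trans + emit


def plan_windows(
    sequence_length: int,
    state_count: int,
    winsize_override: int | None = None,
    overlap_override: int | None = None,
    *,
    k: int = 100,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
) -> WindowPlan:
    """Tile a sequence into overlapping decode windows.

    Window size defaults to the per-thread memory budget divided by the
    state count (8-byte cells), clamped below by ``max(10 k, 2 overlap)``
    and above by the sequence length; overlap defaults to ``max(1000, 4 k)``
    so that any repeat of modeled period is seen whole in some window.
    """
    if sequence_length < 1:
        raise ValueError("sequence_length must be >= 1")
    overlap = overlap_override if overlap_override is not None else max(1000, 4 * k)
    if winsize_override is not None:
        window = winsize_override
    else:
        window = memory_budget // (max(state_count, 1) * CELL_BYTES)
        window = max(window, 10 * k, 2 * overlap)
    window = min(window, sequence_length)
    if sequence_length <= window:
        return WindowPlan(window, 0, ((0, sequence_length),))
    if overlap >= window:
        raise ConfigurationError(f"overlap {overlap} must be smaller than window {window}")
    step = window - overlap
    windows = []
    start = 0
    while True:
        end = start + window
        if end >= sequence_length:
            windows.append((start, sequence_length))
            break
        windows.append((start, end))
        start += step
    return WindowPlan(window, overlap, tuple(windows))


def estimate_memory(plan: WindowPlan, state_count: int, threads: int = 1) -> int:
    """Expected peak decode footprint: window x states x cell bytes x threads."""
    if not plan.windows or plan.windows[0][1] == 0:
        return 0
    actual = min(plan.window_size, plan.windows[0][1] - plan.windows[0][0])
    return actual * state_count * CELL_BYTES * threads


def decode_windowed(
    sequence,
    params: ModelParams | None = None,
    state_space: StateSpace | None = None,
    plan: WindowPlan | None = None,
    threads: int = 1,
) -> DecodedPath:
    """Decode a long sequence window by window and stitch one global path.

    Windows are decoded independently (safely in parallel); each window
    contributes the labels of its core region, with cuts at overlap
    midpoints.  A sequence that fits in a single window is decoded exactly
    as by :func:`viterbi_decode`.  The stitched path's running score is
    rebuilt from the stitched labels.
    """
    if params is None:
        if state_space is None:
            raise ValueError("provide params or a state space")
        params = state_space.params
    if isinstance(sequence, str):
        seq = params.alphabet.encode(sequence)
    else:
        seq = np.asarray(sequence, dtype=np.int8)
    L = len(seq)
    if plan is None:
        from .model import explicit_state_count

        plan = plan_windows(max(L, 1), explicit_state_count(params), k=params.k)
    if L == 0 or len(plan.windows) == 1:
        return viterbi_decode(seq, params)

    def decode_one(bounds):
        s, e = bounds
        try:
            return viterbi_decode(seq[s:e], params)
        except Exception as err:  # pragma: no cover - context for window errors
            raise RuntimeError(f"decoding failed in window [{s}, {e})") from err

    if threads > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=threads) as pool:
            sub_paths = list(pool.map(decode_one, plan.windows))
    else:
        sub_paths = [decode_one(w) for w in plan.windows]

    kind = np.zeros(L, dtype=np.int8)
    period = np.zeros(L, dtype=np.int16)
    look_back = np.zeros(L, dtype=np.int16)
    chain_pos = np.zeros(L, dtype=np.int16)
    del_before = np.zeros(L, dtype=np.int16)
    prev_cut = 0
    for w, ((ws, we), sub) in enumerate(zip(plan.windows, sub_paths)):
        cut = L if w == len(plan.windows) - 1 else plan.windows[w + 1][0] + plan.overlap // 2
        lo, hi = prev_cut - ws, cut - ws
        sl = slice(prev_cut, cut)
        kind[sl] = sub.kind[lo:hi]
        period[sl] = sub.period[lo:hi]
        look_back[sl] = sub.look_back[lo:hi]
        chain_pos[sl] = sub.chain_pos[lo:hi]
        del_before[sl] = sub.del_before[lo:hi]
        prev_cut = cut
    path = DecodedPath(
        kind, period, look_back, chain_pos, del_before,
        np.zeros(L), params, seq,
    )
    path._contribs = path_contributions(path, seq, params)
    path.cumulative_log = np.cumsum(path._contribs)
    return path
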