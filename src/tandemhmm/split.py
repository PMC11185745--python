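"""Subrepeat splitting: find changes of repetitive pattern inside a region.

A period-p repeat state only compares each letter with the letter p back, so
a switch from one unit to another of the same period ("AC...AC GC...GC")
costs a single mismatch and goes unnoticed during decoding.  Splitting is a
post-processing pass: letters are assigned cyclic profile indices 1..p
(insertions get '*', deletions skip indices), two adjacent windows slide
along the repeat building per-index letter-frequency profiles, and peaks in
the divergence between the two window profiles mark pattern changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lcm

import numpy as np
from scipy.signal import find_peaks

from .decode import DecodedPath, I as KIND_I
from .model import DNA, Alphabet

__all__ = [
    "SubRepeat",
    "RepeatProfile",
    "DEFAULT_SPLIT_VAL",
    "assign_profile_indices",
    "build_profile",
    "jsd",
    "find_splits",
    "canonical_unit",
    "consensus_unit",
    "merge_equivalent",
    "split_region",
    "unit_similarity",
    "refine_changepoint",
    "pattern_changes",
]

# A repeat profile is a plain (p, |sigma|) float array; rows are profile
# indices, columns alphabet letters.
RepeatProfile = np.ndarray

# Divergence threshold for declaring a repeat split.  Calibrated so that
# single-pattern repeats with substitution rates up to 20% produce a false
# pattern change in at most 1% of cases (see docs/methods.md).
DEFAULT_SPLIT_VAL = 2.5


@dataclass
class SubRepeat:
    """A maximal single-pattern segment of a repeat region.

    ``start``/``end`` are absolute 0-based half-open sequence coordinates;
    the subrepeats of a region tile its raw (unadjusted) span.
    """

    start: int
    end: int
    pattern: str
    canonical_unit: str


def assign_profile_indices(letters, kinds, del_before, p: int):
    """Cyclic profile indices 1..p for the letters of a repeat region.

    Inserted letters are marked ``'*'`` and do not advance the cycle;
    a deletion run of length j (recorded on the following position)
    advances the cycle by j without consuming letters.
    """
    out = []
    idx = 1
    for t in range(len(letters)):
        if kinds is not None and kinds[t] == KIND_I:
            out.append("*")
            continue
        if del_before is not None and del_before[t]:
            idx = (idx - 1 + int(del_before[t])) % p + 1
        out.append(idx)
        idx = idx % p + 1
    return out


def build_profile(
    letters: np.ndarray,
    indices,
    p: int,
    *,
    pseudocount: float = 0.5,
    alphabet: Alphabet = DNA,
) -> np.ndarray:
    """p x |sigma| letter-frequency profile with pseudocounts, rows normalized.

    ``letters`` is an encoded window of the region; ``indices`` its profile
    indices.  Ambiguity letters and inserted ('*') letters are not counted.
    """
    counts = np.full((p, alphabet.size), pseudocount, dtype=np.float64)
    amb = alphabet.ambiguity_index
    for letter, idx in zip(letters, indices):
        if idx == "*" or letter == amb:
            continue
        counts[idx - 1, letter] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def jsd(L: np.ndarray, R: np.ndarray) -> float:
    """Profile divergence: half the symmetrized Kullback-Leibler sum.

    -1/2 sum_i sum_c [ L_ic log(R_ic / L_ic) + R_ic log(L_ic / R_ic) ];
    symmetric, non-negative, zero iff the profiles are identical.  Entries
    must be strictly positive (guaranteed by pseudocounting).
    """
    L = np.asarray(L, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if L.shape != R.shape:
        raise ValueError(f"profile shapes differ: {L.shape} vs {R.shape}")
    log_ratio = np.log(R) - np.log(L)
    return float(-0.5 * np.sum(L * log_ratio - R * log_ratio))


def profile_window_length(p: int) -> int:
    """Letters per side window: at least twelve observations per profile row."""
    return max(12 * p, 60)


def find_splits(
    letters: np.ndarray,
    indices,
    p: int,
    *,
    split_val: float = DEFAULT_SPLIT_VAL,
    window_len: int | None = None,
    alphabet: Alphabet = DNA,
) -> list[int]:
    """Positions (offsets into ``letters``) where the repetitive pattern changes.

    At every admissible boundary the divergence between the profiles of the
    adjacent left and right windows is computed; strict local maxima above
    ``split_val``, at least one window length apart, are reported.
    """
    w = window_len or profile_window_length(p)
    n = len(letters)
    if n < 2 * w:
        return []
    values = np.empty(n - 2 * w + 1)
    for off, b in enumerate(range(w, n - w + 1)):
        left = build_profile(letters[b - w : b], indices[b - w : b], p, alphabet=alphabet)
        right = build_profile(letters[b : b + w], indices[b : b + w], p, alphabet=alphabet)
        values[off] = jsd(left, right)
    if not np.isfinite(split_val):
        return [] if split_val > 0 else list(range(w, n - w + 1))
    peaks, _ = find_peaks(values, height=split_val, distance=w)
    return [int(pk) + w for pk in peaks]


def canonical_unit(pattern: str) -> str:
    """Lexicographically smallest rotation of a repeat unit.

    All rotations of a unit name the same repeat, so the minimal rotation is
    used as the canonical name (e.g. 'GTTG', 'TTGG' and 'TGGT' all map to
    'GGTT').
    """
    if not pattern:
        raise ValueError("empty pattern")
    return min(pattern[r:] + pattern[:r] for r in range(len(pattern)))


def consensus_unit(profile_counts: np.ndarray, alphabet: Alphabet = DNA) -> str:
    """Majority letter at each profile index; ties resolved in alphabet order.

    A row with no observations (all-ambiguous column) yields the ambiguity
    letter.
    """
    unit = []
    for row in profile_counts:
        if row.max() <= 0:
            unit.append(alphabet.ambiguity)
        else:
            unit.append(alphabet.letters[int(np.argmax(row))])
    return "".join(unit)


def _consensus_for_span(letters, indices, p, alphabet=DNA):
    counts = np.zeros((p, alphabet.size), dtype=np.float64)
    amb = alphabet.ambiguity_index
    for letter, idx in zip(letters, indices):
        if idx == "*" or letter == amb:
            continue
        counts[idx - 1, letter] += 1.0
    return consensus_unit(counts, alphabet)


def merge_equivalent(subrepeats: list[SubRepeat], letters=None, indices=None,
                     offset: int = 0, p: int | None = None,
                     alphabet: Alphabet = DNA) -> list[SubRepeat]:
    """Remove splits between neighbours with rotation-equivalent patterns.

    Undetected indels misalign profile indices and can fake a pattern
    change; a split whose two sides share the same canonical unit is
    spurious and is removed, merging the neighbours.  Applied to fixpoint.
    """
    out = list(subrepeats)
    merged = True
    while merged and len(out) > 1:
        merged = False
        for a in range(len(out) - 1):
            if out[a].canonical_unit == out[a + 1].canonical_unit:
                lo, hi = out[a].start, out[a + 1].end
                if letters is not None and p is not None:
                    pattern = _consensus_for_span(
                        letters[lo - offset : hi - offset],
                        indices[lo - offset : hi - offset], p, alphabet)
                else:
                    pattern = out[a].pattern
                out[a : a + 2] = [SubRepeat(lo, hi, pattern, canonical_unit(pattern))]
                merged = True
                break
    return out


def unit_similarity(u1: str, u2: str) -> float:
    """Best rotation identity between two units, tiled to a common length.

    Units of different periods are expanded to the least common multiple of
    their lengths before comparing rotations, so a harmonic of a pattern
    ('TTT' vs 'T') scores identity 1.
    """
    if not u1 or not u2:
        raise ValueError("empty unit")
    n = lcm(len(u1), len(u2))
    t1 = (u1 * (n // len(u1)))
    t2 = (u2 * (n // len(u2)))
    best = 0
    for r in range(n):
        rot = t1[r:] + t1[:r]
        best = max(best, sum(a == b for a, b in zip(rot, t2)))
    return best / n


def _anchor_phase(seq, unit_idx, pos: int, direction: str) -> int:
    """Rotation offset r such that unit[(t - pos + r) % p] best matches the
    letters adjacent to ``pos`` (left of it or right of it)."""
    p = len(unit_idx)
    span = min(3 * p, 60)
    if direction == "left":
        ts = range(max(0, pos - span), pos)
    else:
        ts = range(pos, min(len(seq), pos + span))
    best, best_r = -1, 0
    for r in range(p):
        sc = sum(1 for t in ts if seq[t] == unit_idx[(t - pos + r) % p])
        if sc > best:
            best, best_r = sc, r
    return best_r


def refine_changepoint(seq: np.ndarray, cut: int, left_unit: str, right_unit: str,
                       scan: int, alphabet: Alphabet = DNA) -> int:
    """Sharpen a pattern-change position by aligning against both units.

    Tiles the left and right consensus units across a window around the
    candidate cut (phases anchored on the adjacent sequence) and places the
    boundary where the prefix of left-matches-minus-right-matches is
    maximal — the maximum-likelihood changepoint between the two templates
    under a symmetric match/mismatch model.
    """
    enc = {c: i for i, c in enumerate(alphabet.letters + alphabet.ambiguity)}
    uL = [enc[c] for c in left_unit]
    uR = [enc[c] for c in right_unit]
    rL = _anchor_phase(seq, uL, cut, "left")
    rR = _anchor_phase(seq, uR, cut, "right")
    lo, hi = max(0, cut - scan), min(len(seq), cut + scan)
    if hi <= lo:
        return cut
    diffs = np.empty(hi - lo)
    for t in range(lo, hi):
        m_left = 1.0 if seq[t] == uL[(t - cut + rL) % len(uL)] else 0.0
        m_right = 1.0 if seq[t] == uR[(t - cut + rR) % len(uR)] else 0.0
        diffs[t - lo] = m_left - m_right
    prefix = np.concatenate(([0.0], np.cumsum(diffs)))
    return lo + int(np.argmax(prefix))


def split_region(region, path: DecodedPath, *, split_val: float | None = None,
                 window_len: int | None = None) -> list[SubRepeat]:
    """Split one annotated region into subrepeats and name its units.

    Fills ``region.subrepeats`` and ``region.unit`` (the canonical unit of
    the region's dominant pattern) and returns the subrepeat list.
    """
    sv = DEFAULT_SPLIT_VAL if split_val is None else split_val
    p = region.period
    alphabet = path.params.alphabet
    t0, t1 = region.raw_start, region.end
    letters = path.sequence[t0:t1]
    indices = assign_profile_indices(letters, path.kind[t0:t1], path.del_before[t0:t1], p)
    cuts = find_splits(letters, indices, p, split_val=sv, window_len=window_len,
                       alphabet=alphabet)

    def build(bounds):
        subs = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            pattern = _consensus_for_span(letters[lo:hi], indices[lo:hi], p, alphabet)
            subs.append(SubRepeat(t0 + lo, t0 + hi, pattern, canonical_unit(pattern)))
        return subs

    n = t1 - t0
    subs = build([0] + cuts + [n])
    if cuts:
        # sharpen each cut against the consensus units on either side
        w = window_len or profile_window_length(p)
        refined = sorted({
            min(max(refine_changepoint(letters, sub.end - t0, sub.pattern,
                                       nxt.pattern, scan=w, alphabet=alphabet), 1), n - 1)
            for sub, nxt in zip(subs[:-1], subs[1:])
        })
        subs = build([0] + refined + [n])
    subs = merge_equivalent(subs, letters, indices, offset=t0, p=p, alphabet=alphabet)
    region.subrepeats = subs
    longest = max(subs, key=lambda s: s.end - s.start)
    region.unit = longest.canonical_unit
    return subs


def pattern_changes(regions, seq: np.ndarray, *, max_gap: int = 50,
                    similarity_threshold: float = 0.5,
                    alphabet: Alphabet = DNA) -> list[int]:
    """Positions where the repetitive pattern changes across an annotation.

    Chains the subrepeats of all regions in order and reports the refined
    boundary between consecutive segments whose units are genuinely
    different (rotation/harmonic similarity at or below the threshold) and
    whose spans are separated by at most ``max_gap`` unannotated letters.
    Segments with equivalent units — decode fragments of one underlying
    repeat, possibly annotated at a harmonic period — are merged silently.
    """
    segs: list[SubRepeat] = []
    for region in sorted(regions, key=lambda r: r.start):
        segs.extend(region.subrepeats)
    merged: list[SubRepeat] = []
    for s in segs:
        if (merged and s.start - merged[-1].end <= max_gap
                and unit_similarity(merged[-1].canonical_unit,
                                    s.canonical_unit) > similarity_threshold):
            prev = merged[-1]
            merged[-1] = SubRepeat(prev.start, s.end, prev.pattern, prev.canonical_unit)
        else:
            merged.append(s)
    changes = []
    for a, b in zip(merged[:-1], merged[1:]):
        gap = b.start - a.end
        if gap <= max_gap:
            # decode fragment boundaries jitter; widen the scan while the
            # maximum-likelihood changepoint keeps landing on its edge
            cut = (a.end + b.start) // 2
            scan = max(gap, 2 * max(len(a.pattern), len(b.pattern)), 20) + 10
            margin = max(len(a.pattern), len(b.pattern), 3)
            for _ in range(4):
                refined = refine_changepoint(seq, cut, a.pattern, b.pattern,
                                             scan, alphabet=alphabet)
                if abs(refined - cut) < scan - margin:
                    break
                cut, scan = refined, scan * 2
            changes.append(refined)
    return changes
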