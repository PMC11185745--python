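"""Seeded generators for random sequence and synthetic tandem repeats.

These generators define the study conditions for the benchmark experiments:
i.i.d. AT-biased background sequence, point-substitution mutagenesis, and
two-subrepeat test cases (two concatenated 500 nt perfect repeats whose
units share at most 50% rotation similarity) used to measure splitting
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DNA, Alphabet, ModelParams

__all__ = [
    "SplitCase",
    "random_sequence",
    "rotation_similarity",
    "mutate",
    "make_split_case",
    "splitting_accuracy",
    "repeat_sequence",
]

CASE_LENGTH = 1000
TRUE_BOUNDARY = 500


@dataclass(frozen=True)
class SplitCase:
    """One two-subrepeat test sequence with its generating truth."""

    sequence: str
    true_boundary: int
    period: int
    unit_left: str
    unit_right: str
    substitution_rate: float
    seed: int


def random_sequence(length: int, at_richness: float = 0.6, seed: int = 0,
                    alphabet: Alphabet = DNA) -> str:
    """i.i.d. sequence with P(A)=P(T)=at/2 and P(C)=P(G)=(1-at)/2."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    probs = [at_richness / 2 if c in "AT" else (1 - at_richness) / 2
             for c in alphabet.letters]
    draws = rng.choice(alphabet.size, size=length, p=probs)
    return "".join(alphabet.letters[i] for i in draws)


def repeat_sequence(unit: str, length: int) -> str:
    """A perfect tandem repeat of ``unit`` truncated to ``length`` letters."""
    reps = -(-length // len(unit))
    return (unit * reps)[:length]


def rotation_similarity(u1: str, u2: str) -> float:
    """Best positionwise identity between u2 and any rotation of u1."""
    if len(u1) != len(u2):
        raise ValueError("units must have equal length")
    n = len(u1)
    best = 0
    for r in range(n):
        rot = u1[r:] + u1[:r]
        best = max(best, sum(a == b for a, b in zip(rot, u2)))
    return best / n


def mutate(sequence: str, substitution_rate: float, seed: int = 0,
           alphabet: Alphabet = DNA) -> str:
    """Substitute each position independently with the given rate.

    A mutated letter is replaced uniformly by one of the other alphabet
    letters (never by itself); ambiguity letters are left untouched.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(sequence)
    hits = np.flatnonzero(rng.random(len(sequence)) < substitution_rate)
    for t in hits:
        c = out[t]
        if c not in alphabet.letters:
            continue
        choices = [x for x in alphabet.letters if x != c]
        out[t] = choices[rng.integers(len(choices))]
    return "".join(out)


def _sample_unit_pair(p: int, rng, alphabet: Alphabet = DNA) -> tuple[str, str]:
    """Rejection-sample two period-p units with rotation similarity <= 0.5."""
    while True:
        u1 = "".join(alphabet.letters[i] for i in rng.integers(alphabet.size, size=p))
        u2 = "".join(alphabet.letters[i] for i in rng.integers(alphabet.size, size=p))
        if rotation_similarity(u1, u2) <= 0.5:
            return u1, u2


def make_split_case(p: int, substitution_rate: float, seed: int = 0,
                    alphabet: Alphabet = DNA) -> SplitCase:
    """Build one two-subrepeat case: 500 nt of each unit, then mutate."""
    if not 1 <= p <= TRUE_BOUNDARY:
        raise ValueError("period must be in 1..500")
    rng = np.random.default_rng(seed)
    u1, u2 = _sample_unit_pair(p, rng, alphabet)
    clean = repeat_sequence(u1, TRUE_BOUNDARY) + repeat_sequence(u2, TRUE_BOUNDARY)
    mutated = mutate(clean, substitution_rate, seed=int(rng.integers(2**31)),
                     alphabet=alphabet)
    return SplitCase(mutated, TRUE_BOUNDARY, p, u1, u2, substitution_rate, seed)


def detected_boundaries(case: SplitCase, params: ModelParams | None = None,
                        split_val: float | None = None) -> list[int]:
    """Run the full pipeline on a case; absolute positions of pattern changes.

    Pattern changes are the refined boundaries between annotated segments
    with genuinely different units, chaining subrepeats across decode
    fragments (see :func:`tandemhmm.split.pattern_changes`).
    """
    from .annotate import annotate_sequence
    from .split import pattern_changes

    params = params or ModelParams.for_period(max(10, case.period))
    seq = params.alphabet.encode(case.sequence)
    regions = annotate_sequence(seq, params, windowed=False,
                                split=True, split_val=split_val)
    return pattern_changes(regions, seq, alphabet=params.alphabet)


def splitting_accuracy(
    periods=range(1, 11),
    rates=(0.0, 0.1, 0.2),
    cases_per_condition: int = 200,
    tolerance: int = 10,
    *,
    params: ModelParams | None = None,
    split_val: float | None = None,
    seed: int = 0,
) -> dict[tuple[int, float], float]:
    """Fraction of cases with exactly one detected change within ``tolerance``
    nt of the true boundary, per (period, substitution rate) condition."""
    if cases_per_condition < 1:
        raise ValueError("cases_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    table: dict[tuple[int, float], float] = {}
    for p in periods:
        for rate in rates:
            hits = 0
            for _ in range(cases_per_condition):
                case = make_split_case(p, rate, seed=int(rng.integers(2**31)))
                changes = detected_boundaries(case, params=params, split_val=split_val)
                if len(changes) == 1 and abs(changes[0] - case.true_boundary) <= tolerance:
                    hits += 1
            table[(p, rate)] = hits / cases_per_condition
    return table
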