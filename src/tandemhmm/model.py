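"""Model parameterization and state space for the tandem-repeat HMM.

The model has a single context-blind non-repetitive (NR) state and, for each
period ``p`` in ``1..k``, a context-sensitive repetitive state R(p) whose
emission distribution favours repeating the letter seen ``p`` positions back.
Insertions and deletions inside a repeat temporarily shift that look-back
offset; they are modeled with period-specific I (emitting, context-blind) and
D (silent) states, each of which feeds a chain of exactly ``p`` J-states that
carries the shifted look-back (``p + a`` after ``a`` insertions, ``p - j``
after ``j`` deletions) back to R(p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "Alphabet",
    "DNA",
    "ModelParams",
    "State",
    "StateSpace",
    "gamma",
    "background_prob",
    "repeat_emission_prob",
    "emission_log_ratio_table",
    "build_state_space",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model parameters or window plans."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol alphabet with a single ambiguity letter.

    The default DNA alphabet is A, C, G, T with ambiguity N.  RNA input is
    supported by mapping U onto T before encoding.
    """

    letters: str = "ACGT"
    ambiguity: str = "N"

    def __post_init__(self) -> None:
        if len(set(self.letters)) != len(self.letters) or len(self.letters) < 2:
            raise ConfigurationError("alphabet letters must be unique, size >= 2")

    @property
    def size(self) -> int:
        return len(self.letters)

    @property
    def ambiguity_index(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        """Map a letter to its alphabet index (ambiguity maps to |sigma|)."""
        u = letter.upper()
        if u == "U":
            u = "T"
        if u == self.ambiguity:
            return self.ambiguity_index
        i = self.letters.find(u)
        if i < 0:
            raise ValueError(f"letter {letter!r} not in alphabet {self.letters}+{self.ambiguity}")
        return i

    def encode(self, sequence: str) -> np.ndarray:
        """Encode a sequence string as int8 indices; raises on foreign letters.

        The error names the first offending position (0-based).
        """
        table = np.full(256, -1, dtype=np.int8)
        for i, c in enumerate(self.letters):
            table[ord(c)] = i
            table[ord(c.lower())] = i
        table[ord("U")] = table[ord("u")] = table[ord("T")]
        amb = self.ambiguity_index
        table[ord(self.ambiguity)] = table[ord(self.ambiguity.lower())] = amb
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        enc = table[raw]
        if (enc < 0).any():
            pos = int(np.argmax(enc < 0))
            raise ValueError(
                f"invalid letter {sequence[pos]!r} at position {pos}; "
                f"expected one of {self.letters}/{self.ambiguity}"
            )
        return enc

    def decode(self, encoded: np.ndarray) -> str:
        symbols = self.letters + self.ambiguity
        return "".join(symbols[i] for i in encoded)


DNA = Alphabet()


@dataclass(frozen=True)
class ModelParams:
    """All tunable probabilities and bounds of the repeat HMM.

    Parameters
    ----------
    k : maximum repeat period modeled (R states exist for periods 1..k).
    lambda_decay : decay of the period prior; the probability of entering a
        period-p repeat is proportional to ``lambda_decay ** p``.
    nu_in : probability of moving from the non-repetitive state into a repeat.
    nu_out : probability of leaving a repetitive state back to background.
    match_prob : probability that a letter inside a period-p repeat equals the
        letter p positions back (must exceed the background chance 1/|sigma|).
    at_richness : background fraction of A+T; A and T each get half of it.
    indel_open : total probability mass a repetitive state spends on opening
        an insertion or a deletion (split evenly between the two).
    indel_extend : probability of extending a run of consecutive indels.
    max_insert, max_delete : bounds i and d on consecutive insertions and
        deletions (defaults 10 and 10).  Deletion runs in a period-p repeat
        are additionally capped at p - 1 so the shifted look-back stays >= 1.
    min_unit : minimum number of full repeat units for a reported annotation.
    """

    k: int = 100
    lambda_decay: float = 0.85
    nu_in: float = 0.02
    nu_out: float = 0.05
    match_prob: float = 0.7
    at_richness: float = 0.6
    indel_open: float = 0.001
    indel_extend: float = 0.2
    max_insert: int = 10
    max_delete: int = 10
    min_unit: int = 2
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be a positive integer")
        if not (0.0 < self.lambda_decay <= 1.0):
            raise ConfigurationError("lambda_decay must be in (0, 1]")
        for name in ("nu_in", "nu_out", "indel_open", "indel_extend"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not (1.0 / self.alphabet.size < self.match_prob < 1.0):
            raise ConfigurationError("match_prob must be in (1/|sigma|, 1)")
        if not (0.0 < self.at_richness < 1.0):
            raise ConfigurationError("at_richness must be in (0, 1)")
        if self.max_insert < 0 or self.max_delete < 0:
            raise ConfigurationError("indel bounds must be >= 0")
        if self.max_delete >= self.k and self.max_delete > 0:
            # A deletion run must leave a positive look-back for at least the
            # largest modeled period; per-period runs are capped at p - 1.
            raise ConfigurationError("max_delete must be smaller than k")
        if self.nu_out + self.indel_open >= 1.0 or self.nu_in >= 1.0:
            raise ConfigurationError("transition mass out of a state exceeds 1")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    @classmethod
    def for_period(cls, k: int, **kwargs) -> "ModelParams":
        """Defaults with the indel bounds capped to fit a small max period."""
        kwargs.setdefault("max_insert", min(10, max(k - 1, 0)))
        kwargs.setdefault("max_delete", min(10, max(k - 1, 0)))
        return cls(k=k, **kwargs)

    def max_delete_for(self, p: int) -> int:
        """Consecutive-deletion cap for period p (look-back p - j >= 1)."""
        return min(self.max_delete, p - 1)

    def indel_off(self) -> "ModelParams":
        return replace(self, max_insert=0, max_delete=0)


def gamma(params: ModelParams, p: int) -> float:
    """Prior probability of entering a period-p repeat rather than another period.

    gamma_p = lambda^p / sum_{i=1..k} lambda^i, so small periods are favoured
    for lambda < 1 and all periods are equally likely at lambda = 1.
    """
    if not 1 <= p <= params.k:
        raise ValueError(f"period {p} outside 1..{params.k}")
    lam = params.lambda_decay
    powers = lam ** np.arange(1, params.k + 1)
    return float(powers[p - 1] / powers.sum())


def gamma_vector(params: ModelParams) -> np.ndarray:
    """gamma_p for p = 1..k as an array (index 0 unused)."""
    lam = params.lambda_decay
    powers = lam ** np.arange(0, params.k + 1)
    powers[0] = 0.0
    return powers / powers.sum()


def background_prob(letter: str | int, params: ModelParams) -> float:
    """Background frequency of a letter: AT-rich composition over A,C,G,T.

    The ambiguity letter returns a neutral placeholder (0.25): it only ever
    enters the decoder through emission/background ratios, where it cancels
    so that ambiguous positions are scored as relative likelihood 1 in
    context-blind states.
    """
    idx = letter if isinstance(letter, int) else params.alphabet.index(letter)
    if idx == params.alphabet.ambiguity_index:
        return 0.25
    base = params.alphabet.letters[idx]
    if base in "AT":
        return params.at_richness / 2.0
    return (1.0 - params.at_richness) / 2.0


def repeat_emission_prob(current: str | int, lookback: str | int, params: ModelParams) -> float:
    """Emission probability of `current` in a repeat state whose look-back letter
    is `lookback`.

    A match emits with probability ``match_prob``; the remaining mass is
    spread over the mismatching letters proportionally to their background
    frequency, so the distribution over the alphabet sums to one for every
    look-back letter.  Ambiguity on either side is a guaranteed mismatch.
    """
    table = emission_log_ratio_table(params)
    c = current if isinstance(current, int) else params.alphabet.index(current)
    b = lookback if isinstance(lookback, int) else params.alphabet.index(lookback)
    return math.exp(table[c, b]) * background_prob(c, params)


from functools import lru_cache


@lru_cache(maxsize=8)
def emission_log_ratio_table(params: ModelParams) -> np.ndarray:
    """(|sigma|+1) x (|sigma|+1) table of log(E / E0) for repeat states.

    Entry [c, b] is the log relative emission likelihood of current letter c
    given look-back letter b.  Ambiguity (last index) is a guaranteed
    mismatch and its background mass is treated as zero in the mismatch
    renormalization, so runs of N score against repeat states.
    """
    n = params.alphabet.size
    amb = params.alphabet.ambiguity_index
    m = params.match_prob
    bg = np.array([background_prob(i, params) for i in range(n)])
    table = np.empty((n + 1, n + 1), dtype=np.float64)
    for b in range(n):
        for c in range(n):
            if c == b:
                table[c, b] = math.log(m / bg[c])
            else:
                table[c, b] = math.log((1.0 - m) / (1.0 - bg[b]))
        table[amb, b] = math.log((1.0 - m) / (1.0 - bg[b]))
    table[:, amb] = math.log(1.0 - m)
    return table


class State(NamedTuple):
    """Descriptor of one explicit HMM state.

    kind is one of "NR", "R", "I", "D", "J"; ``chain_pos`` is the position in
    an I/D run or J-chain (1-based); ``indel`` is the signed indel offset of a
    J-chain (+a after a insertions, -j after j deletions, 0 otherwise);
    ``look_back`` is the emission context distance (0 for NR/I/D).
    """

    kind: str
    period: int
    chain_pos: int
    look_back: int
    indel: int = 0


def explicit_state_count(params: ModelParams) -> int:
    """Closed-form size of the explicit space: 1 + sum_p (1 + i + d + (i+d)p)."""
    i, d, k = params.max_insert, params.max_delete, params.k
    return 1 + sum(1 + i + d + (i + d) * p for p in range(1, k + 1))


class StateSpace:
    """Explicit enumeration of NR, R, I, D and J states with log transitions.

    Deletion runs longer than p - 1 would need a non-positive look-back; the
    corresponding D states and J-chains are still enumerated (so the explicit
    count matches the closed form) but receive no incoming transitions and
    are therefore unreachable during decoding.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        self.states: list[State] = []
        self._index: dict[State, int] = {}
        self._build_states()
        self._transitions: dict[tuple[int, int], float] | None = None

    def _add(self, s: State) -> None:
        self._index[s] = len(self.states)
        self.states.append(s)

    def _build_states(self) -> None:
        p_ = self.params
        self._add(State("NR", 0, 0, 0))
        for p in range(1, p_.k + 1):
            self._add(State("R", p, 0, p))
            for a in range(1, p_.max_insert + 1):
                self._add(State("I", p, a, 0))
            for j in range(1, p_.max_delete + 1):
                self._add(State("D", p, j, 0))
            for a in range(1, p_.max_insert + 1):
                for m in range(1, p + 1):
                    self._add(State("J", p, m, p + a, indel=a))
            for j in range(1, p_.max_delete + 1):
                for m in range(1, p + 1):
                    self._add(State("J", p, m, max(p - j, 0), indel=-j))

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: State) -> int:
        return self._index[state]

    def lookback_after_insertions(self, p: int, insertions: int) -> int:
        """Look-back of the J-chain entered after `insertions` consecutive
        insertions inside a period-p repeat (walks the explicit topology)."""
        j1 = State("J", p, 1, p + insertions, indel=insertions)
        if j1 not in self._index:
            raise ValueError(f"no J-chain for period {p} after {insertions} insertions")
        return j1.look_back

    def lookback_after_deletions(self, p: int, deletions: int) -> int:
        if deletions > self.params.max_delete_for(p):
            raise ValueError(f"period {p} supports at most {self.params.max_delete_for(p)} deletions")
        return State("J", p, 1, p - deletions, indel=-deletions).look_back

    @property
    def transitions(self) -> dict[tuple[int, int], float]:
        """Sparse log-probability transition relation keyed by state indices."""
        if self._transitions is None:
            self._transitions = dict(self._iter_transitions())
        return self._transitions

    def _iter_transitions(self) -> Iterator[tuple[tuple[int, int], float]]:
        p_ = self.params
        gam = gamma_vector(p_)
        idx = self._index
        nr = idx[State("NR", 0, 0, 0)]
        yield (nr, nr), math.log1p(-p_.nu_in)
        rho = p_.indel_extend
        for p in range(1, p_.k + 1):
            r = idx[State("R", p, 0, p)]
            if p_.nu_in > 0:
                yield (nr, r), math.log(p_.nu_in * gam[p])
            d_p = p_.max_delete_for(p)
            open_mass = 0.0
            if p_.max_insert >= 1:
                open_mass += p_.indel_open / 2.0
            if d_p >= 1:
                open_mass += p_.indel_open / 2.0
            if p_.nu_out > 0:
                yield (r, nr), math.log(p_.nu_out)
            stay = 1.0 - p_.nu_out - open_mass
            if stay > 0:
                yield (r, r), math.log(stay)
            # insertion run: R -> I_1 -> ... -> I_a -> J_1(+a) -> ... -> R
            if p_.max_insert >= 1 and p_.indel_open > 0:
                yield (r, idx[State("I", p, 1, 0)]), math.log(p_.indel_open / 2.0)
            for a in range(1, p_.max_insert + 1):
                i_a = idx[State("I", p, a, 0)]
                j1 = idx[State("J", p, 1, p + a, indel=a)]
                if a < p_.max_insert:
                    if rho > 0:
                        yield (i_a, idx[State("I", p, a + 1, 0)]), math.log(rho)
                    if rho < 1:
                        yield (i_a, j1), math.log1p(-rho)
                else:
                    yield (i_a, j1), 0.0
            # deletion run (silent): R -> D_1 -> ... -> D_j -> J_1(-j) -> ... -> R
            if d_p >= 1 and p_.indel_open > 0:
                yield (r, idx[State("D", p, 1, 0)]), math.log(p_.indel_open / 2.0)
            for j in range(1, p_.max_delete + 1):
                d_j = idx[State("D", p, j, 0)]
                j1 = idx[State("J", p, 1, max(p - j, 0), indel=-j)]
                if j < d_p:
                    if rho > 0:
                        yield (d_j, idx[State("D", p, j + 1, 0)]), math.log(rho)
                    if rho < 1:
                        yield (d_j, j1), math.log1p(-rho)
                else:
                    # final usable deletion (or an unreachable overshoot state):
                    # all remaining mass enters the J-chain
                    yield (d_j, j1), 0.0
            # J-chains are deterministic
            for o_sign, bound in ((1, p_.max_insert), (-1, p_.max_delete)):
                for run in range(1, bound + 1):
                    o = o_sign * run
                    lb = p + o if o > 0 else max(p + o, 0)
                    for m in range(1, p):
                        yield (
                            idx[State("J", p, m, lb, indel=o)],
                            idx[State("J", p, m + 1, lb, indel=o)],
                        ), 0.0
                    yield (idx[State("J", p, p, lb, indel=o)], r), 0.0


def build_state_space(params: ModelParams) -> StateSpace:
    """Construct the explicit logical state space for the given parameters."""
    space = StateSpace(params)
    assert len(space) == explicit_state_count(params)
    return space
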