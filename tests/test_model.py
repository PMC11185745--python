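import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemhmm.model import (
    ConfigurationError,
    DNA,
    ModelParams,
    background_prob,
    build_state_space,
    explicit_state_count,
    gamma,
    repeat_emission_prob,
)


class TestGamma:
    @pytest.mark.parametrize(
        "lam, k, p, expected",
        [(1.0, 4, 2, 0.25), (0.5, 2, 1, 2 / 3)],
    )
    def test_examples(self, lam, k, p, expected):
        params = ModelParams(k=k, lambda_decay=lam, max_delete=0, max_insert=0)
        assert gamma(params, p) == pytest.approx(expected)

    def test_out_of_range_period(self):
        params = ModelParams(k=3, max_delete=2)
        with pytest.raises(ValueError):
            gamma(params, 4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(lam=st.floats(0.05, 1.0), k=st.integers(1, 60))
    def test_normalization(self, lam, k):
        params = ModelParams(k=k, lambda_decay=lam, max_insert=0, max_delete=0)
        assert math.isclose(sum(gamma(params, p) for p in range(1, k + 1)), 1.0)


class TestEmissions:
    def test_background_composition(self):
        p5 = ModelParams(at_richness=0.5)
        assert background_prob("A", p5) == pytest.approx(0.25)
        p6 = ModelParams(at_richness=0.6)
        assert background_prob("G", p6) == pytest.approx(0.2)
        assert background_prob("T", p6) == pytest.approx(0.3)

    def test_ambiguity_is_ratio_neutral(self):
        # N in a context-blind state must contribute relative likelihood 1
        from tandemhmm.model import emission_log_ratio_table

        params = ModelParams()
        table = emission_log_ratio_table(params)
        n = DNA.ambiguity_index
        # guaranteed-mismatch contract: N never scores as a repeat
        assert np.all(table[n, :] < 0)
        assert np.all(table[:, n] < 0)

    def test_match_probability(self):
        params = ModelParams(match_prob=0.9)
        assert repeat_emission_prob("A", "A", params) == pytest.approx(0.9)

    def test_uniform_background_mismatch(self):
        params = ModelParams(match_prob=0.7, at_richness=0.5)
        assert repeat_emission_prob("C", "A", params) == pytest.approx(0.1)

    @pytest.mark.parametrize("lookback", "ACGT")
    def test_distribution_sums_to_one(self, lookback):
        params = ModelParams(match_prob=0.77, at_richness=0.63)
        total = sum(repeat_emission_prob(c, lookback, params) for c in "ACGT")
        assert total == pytest.approx(1.0, abs=1e-12)


class TestStateSpace:
    def test_degenerate_model_has_two_states(self):
        params = ModelParams(k=1, max_insert=0, max_delete=0)
        space = build_state_space(params)
        assert len(space) == 2
        assert {s.kind for s in space.states} == {"NR", "R"}

    def test_explicit_count_closed_form(self):
        params = ModelParams(k=5, max_insert=3, max_delete=3)
        space = build_state_space(params)
        # 1 + sum_{p=1..5} (1 + 3 + 3 + 6p) = 126
        assert len(space) == 126
        assert explicit_state_count(params) == 126

    def test_lookback_shift_after_insertions(self):
        space = build_state_space(ModelParams(k=5, max_insert=3, max_delete=3))
        assert space.lookback_after_insertions(5, 3) == 8

    def test_lookback_shift_after_deletions(self):
        space = build_state_space(ModelParams(k=5, max_insert=3, max_delete=3))
        assert space.lookback_after_deletions(5, 2) == 3
        with pytest.raises(ValueError):
            space.lookback_after_deletions(2, 2)  # look-back would hit zero

    def test_lookback_arithmetic_by_walking_topology(self, tiny_params):
        """After a insertions the J-chain look-back is p+a; after j deletions
        it is p-j; verified by walking the explicit transition relation."""
        space = build_state_space(ModelParams(k=6, max_insert=4, max_delete=4))
        states = space.states
        for (u, v), _ in space.transitions.items():
            su, sv = states[u], states[v]
            if su.kind == "I" and sv.kind == "J":
                assert sv.look_back == sv.period + su.chain_pos
            if su.kind == "D" and sv.kind == "J" and su.chain_pos < sv.period:
                # reachable deletion chains only (j <= p - 1)
                assert sv.look_back == sv.period - su.chain_pos

    def test_outgoing_mass_sums_to_one(self):
        params = ModelParams(k=6, max_insert=2, max_delete=2,
                             indel_open=0.03, nu_in=0.04, nu_out=0.05)
        space = build_state_space(params)
        mass = np.zeros(len(space))
        for (u, _), logp in space.transitions.items():
            mass[u] += math.exp(logp)
        assert np.allclose(mass, 1.0, atol=1e-12)

    def test_delete_bound_must_stay_below_k(self):
        with pytest.raises(ConfigurationError):
            ModelParams(k=5, max_delete=5)

    def test_for_period_caps_indel_bounds(self):
        params = ModelParams.for_period(3)
        assert params.max_delete == 2 and params.k == 3


class TestAlphabet:
    def test_encode_round_trip_and_rna(self):
        enc = DNA.encode("acgUuN")
        assert list(enc) == [0, 1, 2, 3, 3, 4]

    def test_foreign_letter_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            DNA.encode("AC-GT")
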