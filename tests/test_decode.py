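import numpy as np
import pytest

from oracle import explicit_viterbi

from tandemhmm.model import ConfigurationError, ModelParams, build_state_space, explicit_state_count
from tandemhmm.decode import (
    WindowPlan,
    decode_windowed,
    estimate_memory,
    plan_windows,
    viterbi_decode,
)
from tandemhmm.annotate import path_to_regions
from tandemhmm.simulate import random_sequence, repeat_sequence

KIND_CODE = {"NR": 0, "R": 1, "I": 2, "J": 3}


class TestViterbi:
    def test_perfect_dinucleotide_repeat(self, tiny_params):
        path = viterbi_decode("ACACACACACACACACACAC", tiny_params)
        # the first p positions have no look-back context; all interior
        # positions must be labeled by the period-2 repetitive state
        assert np.all(path.kind[2:] == 1)
        assert np.all(path.period[2:] == 2)

    def test_unreachable_repeats_without_entry(self):
        params = ModelParams(k=4, nu_in=0.0, max_insert=1, max_delete=1)
        path = viterbi_decode("ACACACACACACAC", params)
        assert np.all(path.kind == 0)

    def test_empty_sequence(self, tiny_params):
        assert len(viterbi_decode("", tiny_params)) == 0

    def test_invalid_letter_position_in_error(self, tiny_params):
        with pytest.raises(ValueError, match="position 3"):
            viterbi_decode("ACGXT", tiny_params)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_explicit_state_oracle(self, seed):
        """Optimized J-chain decoding must agree with a brute-force dynamic
        program that materializes every I/D/J state explicitly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        seq = rng.integers(0, 5, size=n).astype(np.int8)
        k = int(rng.integers(1, 5))
        i = int(rng.integers(0, 2))
        d = min(i, k - 1)
        params = ModelParams(k=k, max_insert=i, max_delete=d,
                             indel_open=0.02, nu_in=0.02, nu_out=0.03)
        score, labels = explicit_viterbi(seq, build_state_space(params))
        path = viterbi_decode(seq, params)
        assert path.cumulative_log[-1] == pytest.approx(score, abs=1e-9)
        assert [KIND_CODE[s.kind] for s in labels] == list(path.kind)
        assert [s.period for s in labels] == list(path.period)

    def test_relative_and_basic_recurrences_agree_on_uniform_background(self):
        """With uniform composition the background ratio is a per-position
        constant, so decoding with raw emissions picks the same path."""
        params = ModelParams(k=3, max_insert=1, max_delete=1, at_richness=0.5,
                             indel_open=0.02, nu_in=0.02, nu_out=0.03)
        space = build_state_space(params)
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = rng.integers(0, 4, size=30).astype(np.int8)
            _, rel = explicit_viterbi(seq, space, relative=True)
            _, basic = explicit_viterbi(seq, space, relative=False)
            assert [s.kind for s in rel] == [s.kind for s in basic]
            assert [s.period for s in rel] == [s.period for s in basic]

    def test_score_additivity(self, tiny_params):
        """Differences of the cumulative log-score reproduce the summed
        log-transition + log-relative-emission terms along the path."""
        seq = random_sequence(300, 0.6, seed=3)
        path = viterbi_decode(seq, tiny_params)
        contribs = path.contributions()
        cum = np.cumsum(contribs)
        assert np.allclose(cum, path.cumulative_log, atol=1e-6)
        a, b = 37, 211
        assert path.cumulative_log[b] - path.cumulative_log[a] == pytest.approx(
            contribs[a + 1 : b + 1].sum(), abs=1e-6)


class TestWindowPlanning:
    def test_short_sequence_is_single_window(self):
        plan = plan_windows(500, 1000, None, None, k=10)
        assert plan.windows == ((0, 500),)
        assert plan.overlap == 0

    def test_stated_tiling(self):
        plan = plan_windows(10_000, 1, 4000, 1000, k=10)
        assert plan.windows == ((0, 4000), (3000, 7000), (6000, 10_000))

    def test_window_size_non_increasing_in_state_count(self):
        sizes = [plan_windows(10**7, m, None, None, k=10).window_size
                 for m in (1000, 10_000, 100_000)]
        assert sizes == sorted(sizes, reverse=True)

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ConfigurationError):
            plan_windows(10_000, 1, 1000, 2000, k=10)

    def test_memory_estimate_is_linear_in_threads(self):
        plan = plan_windows(10_000, 126, 1000, 100, k=5)
        one = estimate_memory(plan, 126, threads=1)
        assert one == 1000 * 126 * 8
        assert estimate_memory(plan, 126, threads=4) == 4 * one

    def test_memory_estimate_empty_sequence(self):
        assert estimate_memory(WindowPlan(0, 0, ((0, 0),)), 126) == 0


class TestWindowedDecode:
    def test_single_window_equivalence(self, tiny_params):
        seq = random_sequence(2000, 0.6, seed=11)
        plan = plan_windows(len(seq), 10, 5000, 100, k=4)
        a = decode_windowed(seq, tiny_params, plan=plan)
        b = viterbi_decode(seq, tiny_params)
        assert np.array_equal(a.kind, b.kind)
        assert np.array_equal(a.cumulative_log, b.cumulative_log)

    def test_boundary_spanning_repeat_is_merged(self):
        """A repeat crossing a window boundary yields one annotation, equal
        to the unwindowed decode."""
        params = ModelParams.for_period(5)
        bg = random_sequence(6000, 0.6, seed=1)
        seq = bg[:3900] + repeat_sequence("ACT", 240) + bg[3900:]
        plan = plan_windows(len(seq), explicit_state_count(params), 4000, 1000, k=5)
        assert len(plan.windows) > 1
        regions_w = path_to_regions(decode_windowed(seq, params, plan=plan), params)
        regions_f = path_to_regions(viterbi_decode(seq, params), params)
        spans_w = [(r.start, r.end, r.period) for r in regions_w]
        spans_f = [(r.start, r.end, r.period) for r in regions_f]
        assert spans_w == spans_f
        assert sum(1 for r in regions_w if r.period == 3 and len(r) > 200) == 1
        for rw, rf in zip(regions_w, regions_f):
            assert rw.score == pytest.approx(rf.score, abs=1e-6)

    def test_thread_count_does_not_change_output(self, tiny_params):
        seq = random_sequence(5000, 0.6, seed=2)
        plan = plan_windows(len(seq), 10, 2000, 500, k=4)
        a = decode_windowed(seq, tiny_params, plan=plan, threads=1)
        b = decode_windowed(seq, tiny_params, plan=plan, threads=4)
        assert np.array_equal(a.kind, b.kind)
        assert np.array_equal(a.cumulative_log, b.cumulative_log)
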