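import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tandemhmm.model import DNA, ModelParams
from tandemhmm.decode import viterbi_decode
from tandemhmm.annotate import path_to_regions
from tandemhmm.split import (
    SubRepeat,
    assign_profile_indices,
    build_profile,
    canonical_unit,
    consensus_unit,
    find_splits,
    jsd,
    merge_equivalent,
    pattern_changes,
    split_region,
    unit_similarity,
)
from tandemhmm.simulate import mutate, repeat_sequence


def _indices_for(seq, insertion_positions=(), p=3):
    kinds = np.ones(len(seq), dtype=np.int8)
    for t in insertion_positions:
        kinds[t] = 2  # insertion label
    dels = np.zeros(len(seq), dtype=np.int16)
    return assign_profile_indices(DNA.encode(seq), kinds, dels, p)


class TestProfileIndices:
    def test_worked_insertion_example(self):
        # 'CATCATCAgTCATCAT' with the g inserted: the cycle skips it
        idx = _indices_for("CATCATCAGTCATCAT", insertion_positions=[8], p=3)
        assert idx == [1, 2, 3, 1, 2, 3, 1, 2, "*", 3, 1, 2, 3, 1, 2, 3]

    def test_perfect_repeat_cycles(self):
        assert _indices_for("ACACAC", p=2) == [1, 2, 1, 2, 1, 2]

    def test_deletion_advances_the_cycle(self):
        seq = DNA.encode("CACAC")
        kinds = np.ones(5, dtype=np.int8)
        dels = np.zeros(5, dtype=np.int16)
        dels[2] = 1  # one letter of the pattern deleted before position 2
        idx = assign_profile_indices(seq, kinds, dels, 3)
        assert idx == [1, 2, 1, 2, 3]  # index 3 skipped at the deletion


class TestJSD:
    def test_identical_profiles_diverge_zero(self):
        L = build_profile(DNA.encode("ACACAC"), [1, 2, 1, 2, 1, 2], 2)
        assert jsd(L, L) == pytest.approx(0.0)

    def test_half_symmetrized_kl_value(self):
        L = np.array([[0.75, 0.25]])
        R = np.array([[0.25, 0.75]])
        assert jsd(L, R) == pytest.approx(0.5 * math.log(3.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jsd(np.ones((2, 4)) / 4, np.ones((3, 4)) / 4)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.dirichlet(np.ones(4), size=3)
        R = rng.dirichlet(np.ones(4), size=3)
        assert jsd(L, R) == pytest.approx(jsd(R, L))
        assert jsd(L, R) >= 0.0


class TestCanonicalUnit:
    @pytest.mark.parametrize("pattern, expected", [
        ("GTTG", "GGTT"),
        ("AAC", "AAC"),
        ("CAT", "ATC"),
    ])
    def test_examples(self, pattern, expected):
        assert canonical_unit(pattern) == expected

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12), st.integers(0, 11))
    def test_rotation_class_function(self, unit, r):
        r = r % len(unit)
        rotated = unit[r:] + unit[:r]
        assert canonical_unit(rotated) == canonical_unit(unit)
        assert canonical_unit(canonical_unit(unit)) == canonical_unit(unit)


class TestConsensus:
    def test_perfect_profile(self):
        counts = np.array([[9, 0, 0, 0], [9, 0, 0, 0], [0, 9, 0, 0]], float)
        assert consensus_unit(counts) == "AAC"

    def test_majority_under_substitutions(self):
        rng = np.random.default_rng(12)
        seq = mutate(repeat_sequence("AAC", 300), 0.1, seed=3)
        enc = DNA.encode(seq)
        idx = [(t % 3) + 1 for t in range(300)]
        counts = np.zeros((3, 4))
        for letter, i in zip(enc, idx):
            counts[i - 1, letter] += 1
        assert consensus_unit(counts) == "AAC"

    def test_ties_break_alphabetically_and_empty_rows_are_ambiguous(self):
        counts = np.array([[5, 5, 0, 0], [0, 0, 0, 0]], float)
        assert consensus_unit(counts) == "AN"


class TestFindSplits:
    def test_homogeneous_repeat_has_no_splits(self):
        seq = DNA.encode(repeat_sequence("AC", 200))
        idx = [(t % 2) + 1 for t in range(200)]
        assert find_splits(seq, idx, 2) == []

    def test_pattern_change_found_near_true_boundary(self):
        seq = DNA.encode(repeat_sequence("AC", 100) + repeat_sequence("GC", 100))
        idx = [(t % 2) + 1 for t in range(200)]
        cuts = find_splits(seq, idx, 2)
        assert len(cuts) == 1
        assert abs(cuts[0] - 100) <= 10

    def test_unreachable_threshold_gives_no_splits(self):
        seq = DNA.encode(repeat_sequence("AC", 100) + repeat_sequence("GC", 100))
        idx = [(t % 2) + 1 for t in range(200)]
        assert find_splits(seq, idx, 2, split_val=float("inf")) == []

    def test_too_short_region_is_unsplittable(self):
        seq = DNA.encode(repeat_sequence("AC", 30))
        idx = [(t % 2) + 1 for t in range(30)]
        assert find_splits(seq, idx, 2) == []


class TestMergeEquivalent:
    def test_rotated_neighbours_are_merged(self):
        subs = [SubRepeat(0, 40, "GTTG", canonical_unit("GTTG")),
                SubRepeat(40, 80, "GGTT", canonical_unit("GGTT"))]
        merged = merge_equivalent(subs)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 80)

    def test_distinct_neighbours_are_kept(self):
        subs = [SubRepeat(0, 40, "AAAC", canonical_unit("AAAC")),
                SubRepeat(40, 80, "GGTT", canonical_unit("GGTT"))]
        assert len(merge_equivalent(subs)) == 2

    def test_single_subrepeat_unchanged(self):
        subs = [SubRepeat(0, 40, "AAC", "AAC")]
        assert merge_equivalent(subs) == subs


class TestUnitSimilarity:
    def test_harmonics_are_identical(self):
        assert unit_similarity("T", "TTT") == 1.0
        assert unit_similarity("AC", "ACAC") == 1.0

    def test_distinct_units(self):
        assert unit_similarity("A", "C") == 0.0


class TestEndToEndSplitting:
    def test_two_pattern_region_splits_once(self):
        params = ModelParams.for_period(4)
        seq = repeat_sequence("AAAC", 400) + repeat_sequence("GGTT", 400)
        enc = params.alphabet.encode(seq)
        path = viterbi_decode(enc, params)
        regions = path_to_regions(path, params)
        changes = []
        for region in regions:
            split_region(region, path)
        changes = pattern_changes(regions, enc)
        assert len(changes) == 1
        assert abs(changes[0] - 400) <= 10
        units = {s.canonical_unit for r in regions for s in r.subrepeats}
        assert units == {"AAAC", "GGTT"}

    def test_subrepeats_tile_the_raw_span(self):
        params = ModelParams.for_period(4)
        seq = repeat_sequence("AAAC", 300) + repeat_sequence("ACGT", 300)
        path = viterbi_decode(seq, params)
        regions = path_to_regions(path, params)
        for region in regions:
            subs = split_region(region, path)
            assert subs[0].start == region.raw_start
            assert subs[-1].end == region.end
            for a, b in zip(subs[:-1], subs[1:]):
                assert a.end == b.start
            for a, b in zip(subs[:-1], subs[1:]):
                assert a.canonical_unit != b.canonical_unit
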