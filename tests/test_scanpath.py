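"""Scanpath construction, truncation, and Levenshtein comparison."""

from __future__ import annotations

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scanpathkit import (
    OFF_AOI,
    Scanpath,
    assign_aoi,
    build_scanpath,
    length_summary,
    levenshtein,
    normalize,
    pairwise_distances,
    truncate,
)

from _oracles import levenshtein_recursive

# the two worked-example scanpaths for the anterolateral STEMI stimulus
P25 = tuple("MMIIMGGEEBAAMMII")
P19 = tuple("HEDDEHHGGGIFFFD")

tokens = st.text(alphabet="ABC", min_size=0, max_size=12).map(tuple)


def sp(seq, pid="P01", sid="ecg"):
    return Scanpath(pid, sid, tuple(seq))


class TestAssignAoi:
    def test_point_inside_aoi(self, ecg_layout):
        b = ecg_layout.aois[1]
        assert assign_aoi((b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2, ecg_layout) == "B"

    def test_point_outside_all_rects(self, ecg_layout):
        assert assign_aoi(-5.0, -5.0, ecg_layout) is OFF_AOI

    def test_matches_bruteforce_containment(self, ecg_layout, rng):
        pts = rng.uniform(-50, 1400, size=(10_000, 2))
        for x, y in pts:
            expected = next(
                (a.label for a in ecg_layout if a.contains(x, y)), OFF_AOI
            )
            assert assign_aoi(x, y, ecg_layout) == expected


class TestBuildScanpath:
    def test_reproduces_worked_example_sequence(self, ecg_layout, fixation_sequence):
        centers = {
            a.label: ((a.x0 + a.x1) / 2, (a.y0 + a.y1) / 2) for a in ecg_layout
        }
        fixations = fixation_sequence([centers[t] for t in P25], pid="P25")
        assert build_scanpath(fixations, ecg_layout).tokens == P25

    def test_off_aoi_policies(self, ecg_layout, fixation_sequence):
        fixations = fixation_sequence([(-10, -10), (-20, -20)])
        assert build_scanpath(fixations, ecg_layout, "drop").tokens == ()
        assert build_scanpath(fixations, ecg_layout, "keep").tokens == (OFF_AOI, OFF_AOI)

    def test_mixed_participants_error(self, ecg_layout, fixation_factory):
        fixations = [
            fixation_factory(pid="P01", onset=0),
            fixation_factory(pid="P02", onset=200),
        ]
        with pytest.raises(ValueError, match="mix"):
            build_scanpath(fixations, ecg_layout)

    def test_unsorted_onsets_error(self, ecg_layout, fixation_factory):
        fixations = [fixation_factory(onset=500), fixation_factory(onset=100)]
        with pytest.raises(ValueError, match="onset"):
            build_scanpath(fixations, ecg_layout)

    def test_empty_input_gives_empty_scanpath(self, ecg_layout):
        assert build_scanpath([], ecg_layout).tokens == ()


class TestTruncate:
    def test_worked_example(self):
        assert truncate(sp("MMMBBABC")).tokens == tuple("MBABC")

    @pytest.mark.parametrize("seq", ["", "A", "MBABC", "AAAA"])
    def test_idempotent(self, seq):
        once = truncate(sp(seq))
        assert truncate(once).tokens == once.tokens

    @given(tokens)
    @settings(max_examples=200, derandomize=True)
    def test_no_adjacent_repeats_and_never_longer(self, seq):
        out = truncate(sp(seq))
        assert len(out) <= len(seq)
        assert all(a != b for a, b in zip(out.tokens, out.tokens[1:]))
        # subsequence of the original, preserving order
        it = iter(seq)
        assert all(any(t == u for u in it) for t in out.tokens)


class TestLevenshtein:
    def test_worked_example_pair_matches_recursive_oracle(self):
        assert levenshtein(P25, P19) == levenshtein_recursive(P25, P19)

    def test_identity_and_empty(self):
        assert levenshtein(P25, P25) == 0
        assert levenshtein((), P19) == len(P19)

    @given(tokens, tokens)
    @settings(max_examples=300, derandomize=True)
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == levenshtein_recursive(a, b)

    @given(tokens, tokens, tokens)
    @settings(max_examples=300, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    @given(tokens, tokens)
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_edlib(self, a, b):
        """Independent cross-check against an external alignment library."""
        assert levenshtein(a, b) == edlib.align("".join(a), "".join(b))["editDistance"]


class TestPairwiseDistances:
    def test_identical_scanpaths_give_zero_matrix(self):
        m = pairwise_distances([sp("AB", "P01"), sp("AB", "P02")])
        np.testing.assert_array_equal(m.values, np.zeros((2, 2)))

    def test_single_insertion(self):
        m = pairwise_distances([sp("A", "P01"), sp("AB", "P02")])
        assert m.values[0, 1] == 1.0

    def test_matches_allpairs_oracle(self, rng):
        paths = [
            sp(rng.choice(list("ABCDE"), size=8), pid=f"P{i}") for i in range(6)
        ]
        m = pairwise_distances(paths)
        for i in range(6):
            for j in range(6):
                assert m.values[i, j] == levenshtein_recursive(
                    paths[i].tokens, paths[j].tokens
                )

    def test_symmetric_zero_diagonal(self, rng):
        paths = [sp(rng.choice(list("ABC"), size=rng.integers(1, 15)), pid=f"P{i}")
                 for i in range(8)]
        m = pairwise_distances(paths)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_duplicate_participant_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_distances([sp("A", "P01"), sp("B", "P01")])


class TestNormalize:
    def test_divides_by_max(self):
        m = pairwise_distances([sp("AAAA", "P01"), sp("", "P02")])
        out = normalize(m)
        assert out.normalized
        np.testing.assert_array_equal(out.values, [[0, 1], [1, 0]])

    def test_degenerate_all_zero_unchanged(self):
        m = pairwise_distances([sp("AB", "P01"), sp("AB", "P02")])
        out = normalize(m)
        assert out.normalized
        np.testing.assert_array_equal(out.values, 0.0)

    def test_preserves_entry_ordering(self, rng):
        paths = [sp(rng.choice(list("ABCD"), size=rng.integers(0, 20)), pid=f"P{i}")
                 for i in range(7)]
        m = pairwise_distances(paths)
        out = normalize(m)
        assert out.values.max() == 1.0
        assert np.array_equal(np.argsort(m.values, axis=None, kind="stable"),
                              np.argsort(out.values, axis=None, kind="stable"))


class TestLengthSummary:
    def test_hand_computed_example(self):
        paths = [sp("A" * n, pid=f"P{i}") for i, n in enumerate([9, 9, 23])]
        s = length_summary(paths)
        assert s.mean == pytest.approx(41 / 3)
        assert s.sd == pytest.approx(np.std([9, 9, 23], ddof=1))
        assert s.mode == 9
        assert s.range == 14

    def test_single_scanpath(self):
        s = length_summary([sp("ABCDEFG")])
        assert (s.mean, s.sd, s.mode, s.range, s.n) == (7.0, 0.0, 7, 0, 1)

    def test_mode_tie_takes_smallest(self):
        paths = [sp("A" * n, pid=f"P{i}") for i, n in enumerate([3, 3, 5, 5])]
        assert length_summary(paths).mode == 3

    def test_truncated_lengths(self):
        paths = [sp("AABBA", "P01"), sp("CCC", "P02")]
        s = length_summary(paths, truncated=True)
        assert s.mean == 2.0  # ABA -> 3 and C -> 1

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            length_summary([])
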