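"""Shannon-entropy profiles and low-complexity-region detection.

The residue-mode profile is checked against a brute-force oracle that
enumerates every window containing each position explicitly.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from llpskit.complexity import (
    LcrRegion,
    detect_lcr_enrichment,
    detect_lcr_entropy,
    merge_regions,
    shannon_block,
    shannon_residue,
)
from llpskit.seqio import AMINO_ACIDS, SequenceRecord
from llpskit.synthetic import embed_block, random_sequence

sequences = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


def entropy_of_window(window: str) -> float:
    """Independent single-window entropy: -sum f log2 f over standard letters."""
    n = len(window)
    total = 0.0
    for aa, count in Counter(window).items():
        if aa == "X":
            continue
        f = count / n
        total -= f * math.log2(f)
    return total


def brute_force_residue_profile(seq: str, n: int) -> list:
    """Oracle: for each position, average entropies of the explicit window list."""
    starts = range(1, len(seq) - n + 2)
    values = []
    for i in range(1, len(seq) + 1):
        windows = [seq[j - 1 : j - 1 + n] for j in starts if j <= i <= j + n - 1]
        values.append(sum(entropy_of_window(w) for w in windows) / len(windows))
    return values


class TestBlockEntropy:
    def test_homopolymer_window_is_zero(self):
        prof = shannon_block(SequenceRecord("t", "AAAAA"), 5)
        assert prof.values.tolist() == [0.0]

    def test_all_distinct_window_is_log2_n(self):
        prof = shannon_block(SequenceRecord("t", "ACDEFGHI"), 8)
        assert prof.values.tolist() == [3.0]

    def test_three_to_one_split(self):
        prof = shannon_block(SequenceRecord("t", "AAAC"), 4)
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert prof.values[0] == pytest.approx(expected, abs=1e-12)

    def test_center_assignment_left_biased(self):
        # N=4 windows on a 6-mer start at 1,2,3 -> centers 2,3,4
        prof = shannon_block(SequenceRecord("t", "ACDEFG"), 4)
        assert prof.positions.tolist() == [2, 3, 4]

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            shannon_block(SequenceRecord("t", "ACD"), 5)

    @given(sequences, st.integers(min_value=2, max_value=20))
    @settings(max_examples=80, deadline=None)
    def test_bounds_and_majority_substitution(self, residues, n):
        if n > len(residues):
            n = len(residues)
        s = SequenceRecord("t", residues)
        prof = shannon_block(s, n)
        bound = min(math.log2(n), math.log2(20)) + 1e-12
        assert (prof.values >= 0).all()
        assert (prof.values <= bound).all()
        # replacing the first window's residues by its majority residue
        # never increases that window's entropy
        window = residues[:n]
        majority = Counter(window).most_common(1)[0][0]
        flattened = majority * n + residues[n:]
        prof2 = shannon_block(SequenceRecord("t", flattened), n)
        assert prof2.values[0] <= prof.values[0] + 1e-12


class TestResidueEntropy:
    def test_homopolymer_all_zero(self):
        prof = shannon_residue(SequenceRecord("t", "AAAA"), 2)
        assert prof.values.tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_position_two_of_aacc(self):
        # windows containing position 2 at N=2: (A,A)=0 and (A,C)=1 -> 0.5
        prof = shannon_residue(SequenceRecord("t", "AACC"), 2)
        assert prof.values[1] == pytest.approx(0.5)

    @given(sequences, st.integers(min_value=2, max_value=12))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, residues, n):
        if n > len(residues):
            n = len(residues)
        s = SequenceRecord("t", residues)
        prof = shannon_residue(s, n)
        oracle = brute_force_residue_profile(residues, n)
        assert np.allclose(prof.values, oracle, atol=1e-9)
        assert prof.values.size == s.length


class TestLcrDetection:
    def test_polyq_block_recovered(self, rng):
        s, start = embed_block(100, "Q" * 30, rng)
        regions = detect_lcr_entropy(s, N=12, threshold_bits=2.2)
        covering = [r for r in regions if r.start <= start and r.end >= start + 29 - 11]
        assert covering, f"no region covering the poly-Q block at {start}"
        assert any("Q" in r.enriched_residues for r in covering)

    def test_random_sequence_rarely_below_half_bit(self, rng):
        hits = 0
        for _ in range(100):
            s = random_sequence(100, rng)
            hits += bool(detect_lcr_entropy(s, N=12, threshold_bits=0.5))
        assert hits == 0

    def test_homopolymer_single_full_region(self):
        s = SequenceRecord("t", "Q" * 40)
        regions = detect_lcr_entropy(s, N=12, threshold_bits=2.2)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 40)
        assert regions[0].mean_entropy == 0.0

    def test_enrichment_regions(self):
        s = SequenceRecord("t", "GGGGGGAAAAAA")
        regions = detect_lcr_enrichment(s, window=6, min_fraction=0.8)
        by_label = {r.label: (r.start, r.end) for r in regions}
        assert by_label["LCR:G"][0] == 1
        assert by_label["LCR:A"][1] == 12

    def test_enrichment_trivial_homopolymer(self):
        regions = detect_lcr_enrichment(SequenceRecord("t", "QQQQ"), window=4,
                                        min_fraction=1.0)
        assert [(r.start, r.end) for r in regions] == [(1, 4)]

    def test_uniform_random_full_fraction_empty(self, rng):
        for _ in range(50):
            s = random_sequence(60, rng)
            if len(set(s.residues)) == 1:  # astronomically unlikely
                continue
            assert detect_lcr_enrichment(s, window=20, min_fraction=1.0) == []


class TestMergeRegions:
    def test_overlap_unions_enrichment_sets(self):
        merged = merge_regions([
            LcrRegion(10, 30, enriched_residues=frozenset("E")),
            LcrRegion(25, 50, enriched_residues=frozenset("G")),
        ])
        assert [(r.start, r.end) for r in merged] == [(10, 50)]
        assert merged[0].enriched_residues == frozenset("EG")

    def test_disjoint_untouched(self):
        merged = merge_regions([LcrRegion(1, 5), LcrRegion(20, 30)], max_gap=0)
        assert [(r.start, r.end) for r in merged] == [(1, 5), (20, 30)]

    def test_gap_within_tolerance_merged(self):
        merged = merge_regions([LcrRegion(1, 5), LcrRegion(8, 10)], max_gap=3)
        assert [(r.start, r.end) for r in merged] == [(1, 10)]

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            merge_regions([LcrRegion(5, 50)], sequence_length=40)

    @given(
        st.lists(
            st.tuples(st.integers(1, 80), st.integers(0, 20)).map(
                lambda t: LcrRegion(t[0], t[0] + t[1])
            ),
            min_size=1, max_size=12,
        ),
        st.integers(0, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_sorted_nonoverlapping(self, regions, max_gap):
        merged = merge_regions(regions, max_gap=max_gap)
        assert merge_regions(merged, max_gap=max_gap) == merged
        for a, b in zip(merged, merged[1:]):
            assert a.end + max_gap < b.start
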