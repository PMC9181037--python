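"""Predictor-track parsing and consensus voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from llpskit.consensus import (
    PredictionTrack,
    binarize_disorder,
    consensus_categorical,
    consensus_disorder,
    contact_consensus,
    read_contact_matrix,
    read_prediction_tracks,
    ss8_to_ss3,
)
from llpskit.errors import FormatError


def dialect_file(tmp_path, rows):
    path = tmp_path / "pred.csv"
    lines = ["position,residue,source,feature,value"]
    lines += [",".join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPredictions:
    def test_three_tool_ss3(self, tmp_path):
        rows = [
            (pos, "A", tool, "ss3", state)
            for tool in ("t1", "t2", "t3")
            for pos, state in enumerate("HHEC", start=1)
        ]
        tracks = read_prediction_tracks(dialect_file(tmp_path, rows))
        assert len(tracks) == 3
        assert all(len(t) == 4 for t in tracks)
        assert tracks[0].values == "HHEC"

    def test_missing_position_rejected(self, tmp_path):
        rows = [(p, "A", "t1", "ss3", "H") for p in (1, 2, 4)]
        with pytest.raises(FormatError):
            read_prediction_tracks(dialect_file(tmp_path, rows))

    def test_probability_out_of_range_rejected(self, tmp_path):
        rows = [(1, "A", "t1", "disorder_prob", 0.3),
                (2, "C", "t1", "disorder_prob", 1.2)]
        with pytest.raises(FormatError):
            read_prediction_tracks(dialect_file(tmp_path, rows))

    def test_invalid_state_letter_rejected(self, tmp_path):
        rows = [(1, "A", "t1", "ss3", "Z")]
        with pytest.raises(FormatError):
            read_prediction_tracks(dialect_file(tmp_path, rows))


class TestSs8Collapse:
    @pytest.mark.parametrize(
        "ss8,ss3",
        [("H", "H"), ("G", "H"), ("I", "H"), ("E", "E"), ("B", "E"),
         ("T", "C"), ("S", "C"), ("C", "C")],
    )
    def test_total_over_eight_letters(self, ss8, ss3):
        t = PredictionTrack("x", "ss8", ss8)
        assert ss8_to_ss3(t).values == ss3

    def test_consensus_commutes_with_collapse(self):
        ss8_tracks = [
            PredictionTrack("a", "ss8", "GIEB"),
            PredictionTrack("b", "ss8", "HGTB"),
            PredictionTrack("c", "ss8", "IHES"),
        ]
        collapsed_first = consensus_categorical(
            [ss8_to_ss3(t) for t in ss8_tracks], "ss3"
        )
        assert "".join(collapsed_first.states) == "HHEE"


class TestCategoricalConsensus:
    def test_majority(self):
        tracks = [PredictionTrack(s, "ss3", v) for s, v in
                  [("a", "H"), ("b", "H"), ("c", "E")]]
        c = consensus_categorical(tracks)
        assert c.states == ["H"]
        assert c.agreement[0] == pytest.approx(2 / 3)

    def test_single_track_idempotent(self):
        t = PredictionTrack("a", "ss3", "HEC")
        c = consensus_categorical([t])
        assert "".join(c.states) == "HEC"
        assert (c.agreement == 1.0).all()

    def test_tie_goes_to_coil_with_flag(self):
        tracks = [PredictionTrack("a", "ss3", "H"), PredictionTrack("b", "ss3", "E")]
        c = consensus_categorical(tracks)
        assert c.states == ["C"]
        assert c.ties[0]

    def test_sa3_tie_goes_to_medium(self):
        tracks = [PredictionTrack("a", "sa3", "B"), PredictionTrack("b", "sa3", "E")]
        assert consensus_categorical(tracks).states == ["M"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_categorical([
                PredictionTrack("a", "ss3", "HH"),
                PredictionTrack("b", "ss3", "H"),
            ])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_idempotence_and_order_invariance(self, data):
        length = data.draw(st.integers(1, 12))
        n = data.draw(st.integers(1, 5))
        tracks = [
            PredictionTrack(
                f"s{k}", "ss3",
                "".join(data.draw(st.sampled_from("HEC")) for _ in range(length)),
            )
            for k in range(n)
        ]
        c = consensus_categorical(tracks)
        # order invariance
        perm = data.draw(st.permutations(tracks))
        c2 = consensus_categorical(perm)
        assert c.states == c2.states
        assert np.allclose(c.agreement, c2.agreement)
        # idempotence: consensus of n copies of the consensus is itself
        copies = [PredictionTrack(f"c{k}", "ss3", "".join(c.states)) for k in range(3)]
        assert consensus_categorical(copies).states == c.states


class TestDisorder:
    @pytest.mark.parametrize("score,disordered", [(0.49, 0), (0.5, 1), (0.0, 0), (1.0, 1)])
    def test_binarization_boundary(self, score, disordered):
        t = PredictionTrack("x", "disorder_prob", np.array([score]))
        assert binarize_disorder(t).values == [disordered]

    def test_two_of_three_vote(self):
        tracks = [PredictionTrack(f"s{i}", "disorder_prob", np.array([p]))
                  for i, p in enumerate([0.6, 0.7, 0.2])]
        track, fraction = consensus_disorder(tracks)
        assert track.states == ["D"]
        assert fraction == 100.0

    def test_all_ordered(self):
        tracks = [PredictionTrack(f"s{i}", "disorder_prob", np.zeros(5))
                  for i in range(3)]
        track, fraction = consensus_disorder(tracks)
        assert fraction == 0.0
        assert track.states == ["O"] * 5

    def test_single_track_equals_own_binarization(self, rng):
        t = PredictionTrack("x", "disorder_prob", rng.random(20))
        track, _ = consensus_disorder([t])
        expected = ["D" if v else "O" for v in binarize_disorder(t).values]
        assert track.states == expected

    def test_adding_all_disordered_track_never_decreases_fraction(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            tracks = [PredictionTrack(f"s{i}", "disorder_prob", rng.random(30))
                      for i in range(n)]
            _, before = consensus_disorder(tracks)
            tracks.append(PredictionTrack("allD", "disorder_prob", np.ones(30)))
            _, after = consensus_disorder(tracks)
            assert after >= before


class TestContacts:
    def test_all_zero_matrix(self):
        t = PredictionTrack("m", "contact_matrix", np.zeros((6, 6)))
        matrix, counts = contact_consensus([t])
        assert matrix.sum() == 0
        assert counts.tolist() == [0] * 6

    def test_single_entry_symmetrized(self):
        m = np.zeros((12, 12))
        m[1, 9] = 0.9  # residues 2 and 10 (0-based indices 1, 9)
        t = PredictionTrack("m", "contact_matrix", m)
        matrix, counts = contact_consensus([t])
        assert matrix[1, 9] == 1 and matrix[9, 1] == 1
        assert counts[1] == 1 and counts[9] == 1
        assert matrix.sum() == 2

    def test_near_diagonal_masked(self):
        m = np.ones((8, 8))
        matrix, _ = contact_consensus([PredictionTrack("m", "contact_matrix", m)])
        idx = np.arange(8)
        sep = np.abs(idx[:, None] - idx[None, :])
        assert (matrix[sep < 3] == 0).all()
        assert (matrix[sep >= 3] == 1).all()

    def test_disagreement_tie_means_no_contact(self):
        a = np.zeros((10, 10)); a[0, 8] = 0.9
        b = np.zeros((10, 10)); b[0, 8] = 0.1
        matrix, _ = contact_consensus([
            PredictionTrack("a", "contact_matrix", a),
            PredictionTrack("b", "contact_matrix", b),
        ])
        assert matrix[0, 8] == 0

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("# contact\n0 1 0\n1 0 0\n")
        with pytest.raises(FormatError):
            read_contact_matrix(path)

    def test_matrix_file_roundtrip(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("# 3x3\n0 0 0.8\n0 0 0\n0.8 0 0\n")
        t = read_contact_matrix(path)
        assert t.values.shape == (3, 3)
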