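"""Consensus over third-party per-residue predictions.

Input dialect: a delimited text file (comma or tab, header required) with
columns ``position, residue, source, feature, value``; one row per residue
per (source, feature) pair, positions 1..L complete. Contact maps are
separate whitespace-delimited L x L grids with a one-line header.

Features: ``ss3`` (H/E/C), ``ss8`` (H/G/I/E/B/T/S/C), ``sa3`` (B/M/E burial),
``disorder_prob`` (probability in [0, 1]), ``contact_matrix``.

The consensus operator is a per-position plurality vote with declared tie
rules: ties go to coil (ss3/ss8), medium burial (sa3), disordered (disorder)
and no-contact (contacts, which require a strict majority). Votes are
order-invariant and idempotent on identical tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError
from .seqio import FeatureTrack

SS3_STATES = frozenset("HEC")
SS8_STATES = frozenset("HGIEBTSC")
SA3_STATES = frozenset("BME")

#: Standard 8-state to 3-state secondary-structure collapse.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}

TIE_STATE = {"ss3": "C", "ss8": "C", "sa3": "M"}


@dataclass
class PredictionTrack:
    """One predictor's per-residue output for one feature."""

    source: str
    feature: str  # ss3 | ss8 | sa3 | disorder_prob | contact_matrix
    values: object  # str for categorical, np.ndarray for numeric/matrix

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConsensusTrack:
    """Per-residue consensus states with agreement bookkeeping."""

    feature: str
    states: list
    agreement: np.ndarray  # winner votes / n_sources
    n_sources: int
    ties: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _validate_categorical(feature: str, states: str, source: str) -> None:
    allowed = {"ss3": SS3_STATES, "ss8": SS8_STATES, "sa3": SA3_STATES}[feature]
    bad = set(states) - allowed
    if bad:
        raise FormatError(
            f"{source}/{feature}: invalid state letters {sorted(bad)}"
        )


def read_prediction_tracks(path) -> list:
    """Parse the uniform prediction dialect into PredictionTracks.

    Validates completeness (positions 1..L once each per source/feature),
    state alphabets, and probability bounds.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse prediction file ({exc})") from exc
    required = {"position", "residue", "source", "feature", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for (source, feature), group in df.groupby(["source", "feature"], sort=True):
        positions = group["position"].to_numpy()
        length = int(positions.max())
        expected = np.arange(1, length + 1)
        if len(positions) != length or not np.array_equal(np.sort(positions), expected):
            raise FormatError(
                f"{path}: {source}/{feature}: positions are not exactly 1..{length}"
            )
        ordered = group.sort_values("position")["value"]
        if feature in ("ss3", "ss8", "sa3"):
            states = "".join(str(v).strip().upper() for v in ordered)
            _validate_categorical(feature, states, str(source))
            values: object = states
        elif feature == "disorder_prob":
            probs = ordered.astype(float).to_numpy()
            if ((probs < 0) | (probs > 1)).any():
                raise FormatError(f"{path}: {source}/disorder_prob outside [0, 1]")
            values = probs
        else:
            raise FormatError(f"{path}: unknown feature {feature!r}")
        tracks.append(PredictionTrack(source=str(source), feature=str(feature), values=values))
    if not tracks:
        raise FormatError(f"{path}: no prediction tracks found")
    return tracks


def read_contact_matrix(path, source: str = "contacts") -> PredictionTrack:
    """Read a whitespace-delimited L x L probability grid (one header line)."""
    lines = Path(path).read_text().splitlines()
    matrix = np.loadtxt(lines[1:], dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError(f"{path}: contact matrix is not square ({matrix.shape})")
    return PredictionTrack(source=source, feature="contact_matrix", values=matrix)


def ss8_to_ss3(t: PredictionTrack) -> PredictionTrack:
    """Collapse an 8-state track to 3 states (H/G/I->H, E/B->E, T/S/C->C)."""
    if t.feature != "ss8":
        raise ValueError(f"expected an ss8 track, got {t.feature!r}")
    try:
        collapsed = "".join(SS8_TO_SS3[ch] for ch in t.values)
    except KeyError as exc:
        raise FormatError(f"{t.source}: unknown ss8 letter {exc.args[0]!r}") from exc
    return PredictionTrack(source=t.source, feature="ss3", values=collapsed)


def consensus_categorical(
    tracks: Iterable[PredictionTrack], feature: Optional[str] = None
) -> ConsensusTrack:
    """Per-position plurality vote over categorical tracks.

    Ties resolve to coil (ss3/ss8) or medium (sa3) and are flagged.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    feature = feature or tracks[0].feature
    if any(t.feature != feature for t in tracks):
        raise ValueError("tracks mix features")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    length = lengths.pop()
    n = len(tracks)
    states, agreement, ties = [], np.empty(length), np.zeros(length, dtype=bool)
    for i in range(length):
        votes = Counter(t.values[i] for t in tracks)
        top = max(votes.values())
        winners = sorted(st for st, v in votes.items() if v == top)
        if len(winners) == 1:
            state = winners[0]
        else:
            state = TIE_STATE.get(feature, winners[0])
            ties[i] = True
        states.append(state)
        agreement[i] = top / n  # plurality share; ties carry the tied share
    return ConsensusTrack(feature=feature, states=states, agreement=agreement,
                          n_sources=n, ties=ties)


def binarize_disorder(t: PredictionTrack, threshold: float = 0.5) -> FeatureTrack:
    """Binary disorder calls: a residue is ordered when its score is strictly
    below the threshold, disordered at or above it."""
    if t.feature != "disorder_prob":
        raise ValueError(f"expected a disorder_prob track, got {t.feature!r}")
    values = [1 if p >= threshold else 0 for p in t.values]
    return FeatureTrack(name=f"disorder_{t.source}", values=values, kind="binary")


def consensus_disorder(
    tracks: Iterable[PredictionTrack], threshold: float = 0.5
) -> tuple:
    """(ConsensusTrack with D/O states, disorder percentage).

    Each track is binarized at the threshold, then a per-position plurality
    vote is taken with ties resolved toward disordered. The fraction is the
    percentage of consensus-disordered positions (0-100).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    binary = [binarize_disorder(t, threshold) for t in tracks]
    lengths = {len(b) for b in binary}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    length = lengths.pop()
    n = len(binary)
    votes = np.sum([b.values for b in binary], axis=0)
    disordered = votes * 2 >= n  # tie -> disordered
    states = ["D" if d else "O" for d in disordered]
    winner_votes = np.where(disordered, votes, n - votes)
    track = ConsensusTrack(
        feature="disorder", states=states,
        agreement=winner_votes / n, n_sources=n,
        ties=(votes * 2 == n),
    )
    fraction = 100.0 * float(disordered.sum()) / length
    return track, fraction


def contact_consensus(
    matrices: Iterable[PredictionTrack],
    prob_threshold: float = 0.5,
    min_separation: int = 3,
) -> tuple:
    """(binary symmetric contact matrix, per-residue contact counts).

    Each probability matrix is binarized at ``prob_threshold``, symmetrized
    (max of the (i, j) and (j, i) entries), and the pair is a consensus
    contact only on a strict majority of sources. Pairs with sequence
    separation |i - j| < min_separation (including the diagonal) are masked.
    """
    mats = []
    for t in matrices:
        m = np.asarray(t.values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"{t.source}: contact matrix is not square")
        binary = (m >= prob_threshold).astype(int)
        mats.append(np.maximum(binary, binary.T))
    if not mats:
        raise ValueError("need at least one contact matrix")
    dims = {m.shape[0] for m in mats}
    if len(dims) != 1:
        raise ValueError(f"contact matrix dimension mismatch: {sorted(dims)}")
    length = dims.pop()
    votes = np.sum(mats, axis=0)
    consensus = (votes * 2 > len(mats)).astype(int)  # strict majority
    idx = np.arange(length)
    mask = np.abs(idx[:, None] - idx[None, :]) < min_separation
    consensus[mask] = 0
    return consensus, consensus.sum(axis=1)
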