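"""Shannon-entropy complexity profiles and low-complexity-region detection.

Two entropy modes are provided, both in bits (log base 2):

* block mode: S(j, N) = -sum_aa f_aa log2 f_aa over the fractions f_aa of the
  20 standard amino acids inside the length-N window starting at j; the value
  is assigned to the window's center position. S ranges from 0 (homopolymer
  window) to min(log2 N, log2 20).
* residue mode: S_i is the mean of S(j, N) over every window fully inside the
  sequence that contains position i. Interior positions average N windows;
  positions within N-1 of a terminus average fewer (no padding is applied).

Low-complexity regions can be called either from the residue-mode profile
(entropy below a threshold) or from per-amino-acid sliding-window enrichment;
overlapping or nearby calls are merged into unified regions whose enriched
residue sets are unioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .seqio import AMINO_ACIDS, SequenceRecord

#: Default window for compositional complexity (within the 5-20 range that is
#: typical for compositional effects).
DEFAULT_WINDOW = 12
#: Residue-mode entropy below this (bits) marks a low-complexity position.
DEFAULT_ENTROPY_THRESHOLD = 2.2
#: Residues occupying at least this fraction of a region are "enriched".
DEFAULT_ENRICHMENT_FLOOR = 0.30
#: Sliding-window fraction for single-residue enrichment regions.
DEFAULT_MIN_FRACTION = 0.45
#: Regions closer than this many residues are merged.
DEFAULT_MAX_GAP = 10


@dataclass
class EntropyProfile:
    """Entropy values in bits: per window center (block) or per residue."""

    mode: str  # "residue" | "block"
    window: int
    positions: np.ndarray  # 1-based positions the values refer to
    values: np.ndarray


@dataclass(frozen=True)
class LcrRegion:
    """A low-complexity region: 1-based inclusive, with enrichment metadata."""

    start: int
    end: int
    label: str = "LCR"
    enriched_residues: frozenset = field(default_factory=frozenset)
    mean_entropy: Optional[float] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _encode(s: SequenceRecord) -> np.ndarray:
    """Residues as integer codes 0..19 for the standard letters, 20 for X."""
    lookup = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    lookup["X"] = 20
    return np.array([lookup[ch] for ch in s.residues], dtype=np.int64)


def _window_counts(codes: np.ndarray, n: int) -> np.ndarray:
    """(n_windows, 21) matrix of residue counts per sliding window."""
    length = codes.size
    onehot = np.zeros((length, 21), dtype=np.float64)
    onehot[np.arange(length), codes] = 1.0
    csum = np.vstack([np.zeros((1, 21)), np.cumsum(onehot, axis=0)])
    return csum[n:] - csum[:-n]


def _check_window(s: SequenceRecord, n: int) -> None:
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    if n > s.length:
        raise ValueError(f"window length {n} exceeds sequence length {s.length}")


def shannon_block(s: SequenceRecord, N: int = DEFAULT_WINDOW) -> EntropyProfile:
    """Window-resolution Shannon entropy, value at each window center.

    Fractions are taken over the 20 standard amino acids with denominator N;
    ``X`` residues dilute the window (they contribute to no letter fraction).
    The center of the window starting at 1-based position j is
    j + floor((N-1)/2) (left-biased for even N).
    """
    _check_window(s, N)
    counts = _window_counts(_encode(s), N)[:, :20]  # drop X column
    f = counts / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    values = -terms.sum(axis=1)
    starts = np.arange(1, s.length - N + 2)
    centers = starts + (N - 1) // 2
    return EntropyProfile(mode="block", window=N, positions=centers, values=values)


def shannon_residue(s: SequenceRecord, N: int = DEFAULT_WINDOW) -> EntropyProfile:
    """Residue-resolution entropy: mean of block entropies over the windows
    containing each position (windows fully inside the sequence only)."""
    _check_window(s, N)
    block = shannon_block(s, N).values  # indexed by window start-1
    n_windows = block.size
    csum = np.concatenate([[0.0], np.cumsum(block)])
    values = np.empty(s.length)
    for i in range(1, s.length + 1):
        first = max(1, i - N + 1)            # first window start containing i
        last = min(i, n_windows)             # last window start containing i
        values[i - 1] = (csum[last] - csum[first - 1]) / (last - first + 1)
    return EntropyProfile(
        mode="residue", window=N, positions=np.arange(1, s.length + 1), values=values
    )


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as 1-based inclusive (start, end) pairs."""
    out = []
    start = None
    for i, flag in enumerate(mask, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _enriched_residues(s: SequenceRecord, start: int, end: int, floor: float) -> frozenset:
    segment = s.residues[start - 1 : end]
    length = len(segment)
    return frozenset(
        aa for aa in AMINO_ACIDS if segment.count(aa) / length >= floor
    )


def detect_lcr_entropy(
    s: SequenceRecord,
    N: int = DEFAULT_WINDOW,
    threshold_bits: float = DEFAULT_ENTROPY_THRESHOLD,
    enrichment_floor: float = DEFAULT_ENRICHMENT_FLOOR,
) -> list:
    """Low-complexity regions from the residue-mode entropy profile.

    Maximal runs of positions with entropy below the threshold are extended
    by half a window on each side (the positions whose windows overlap the
    run), clipped to the sequence, then merged if they touch. Each region is
    annotated with the residues whose in-region frequency reaches
    ``enrichment_floor`` and with the mean entropy of the original run.
    """
    profile = shannon_residue(s, N)
    left, right = (N - 1) // 2, N // 2
    regions = []
    for start, end in _runs(profile.values < threshold_bits):
        ext_start = max(1, start - left)
        ext_end = min(s.length, end + right)
        mean_e = float(profile.values[start - 1 : end].mean())
        regions.append(
            LcrRegion(
                start=ext_start,
                end=ext_end,
                label="LCR",
                enriched_residues=_enriched_residues(s, ext_start, ext_end, enrichment_floor),
                mean_entropy=mean_e,
            )
        )
    return merge_regions(regions, max_gap=0, sequence_length=s.length)


def detect_lcr_enrichment(
    s: SequenceRecord,
    window: int = 20,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list:
    """Single-amino-acid enrichment regions from sliding-window fractions.

    For each amino acid, positions covered by at least one window in which
    the amino acid's fraction reaches ``min_fraction`` are collected into
    maximal regions labeled with that residue. Returns the concatenated,
    sorted list over all amino acids (one region list per residue, flattened).
    """
    if window > s.length:
        window = s.length
    counts = _window_counts(_encode(s), window)[:, :20]
    frac = counts / window
    regions = []
    for ai, aa in enumerate(AMINO_ACIDS):
        qualifying = frac[:, ai] >= min_fraction
        if not qualifying.any():
            continue
        covered = np.zeros(s.length, dtype=bool)
        for w, ok in enumerate(qualifying):
            if ok:
                covered[w : w + window] = True
        for start, end in _runs(covered):
            regions.append(
                LcrRegion(
                    start=start, end=end, label=f"LCR:{aa}",
                    enriched_residues=frozenset(aa),
                )
            )
    return sorted(regions, key=lambda r: (r.start, r.end, r.label))


def merge_regions(
    regions: Iterable[LcrRegion],
    max_gap: int = 0,
    sequence_length: Optional[int] = None,
) -> list:
    """Union overlapping regions (or regions separated by <= max_gap).

    Enriched-residue sets are unioned; mean entropies are combined as a
    length-weighted average of the inputs (an approximation recorded for
    display, not recomputed from a profile). Idempotent: merging a merged
    list changes nothing. Output is sorted and non-overlapping.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    regions = sorted(regions, key=lambda r: (r.start, r.end))
    if sequence_length is not None:
        for r in regions:
            if r.end > sequence_length:
                raise ValueError(
                    f"region [{r.start}, {r.end}] outside sequence of length {sequence_length}"
                )
    merged: list = []
    for region in regions:
        if merged and region.start <= merged[-1].end + max_gap + 1:
            prev = merged[-1]
            entropies = [
                (r.mean_entropy, r.length)
                for r in (prev, region)
                if r.mean_entropy is not None
            ]
            mean_e = (
                sum(e * w for e, w in entropies) / sum(w for _, w in entropies)
                if entropies
                else None
            )
            merged[-1] = LcrRegion(
                start=prev.start,
                end=max(prev.end, region.end),
                label=prev.label if prev.label == region.label else "LCR",
                enriched_residues=prev.enriched_residues | region.enriched_residues,
                mean_entropy=mean_e,
            )
        else:
            merged.append(region)
    return merged
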