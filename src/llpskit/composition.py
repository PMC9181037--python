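"""Amino-acid composition, physicochemical class tracks, and enrichment.

The physicochemical classes follow the residue groupings standard for
phase-separation sequence analysis:

* polar: S, T, Y, Q, N, C, M
* hydrophobic: G, A, V, I, L, P, F
* aromatic: F, Y, W, H
* pi_system: R, N, D, Q, E, G plus the aromatic set (glycine stacks through
  the peptide-bond pi electrons despite having no side chain)
* positive: H, K, R; negative: E, D; charged: their union

Classes overlap by design (e.g. G is hydrophobic and a pi system, H is
positive and aromatic). ``X`` belongs to no class but counts in denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError
from .seqio import AMINO_ACIDS, FeatureTrack, SequenceRecord

_AROMATIC = frozenset("FYWH")

DEFAULT_CLASS_SETS = {
    "polar": frozenset("STYQNCM"),
    "hydrophobic": frozenset("GAVILPF"),
    "aromatic": _AROMATIC,
    "pi_system": frozenset("RNDQEG") | _AROMATIC,
    "positive": frozenset("HKR"),
    "negative": frozenset("ED"),
    "charged": frozenset("HKR") | frozenset("ED"),
    # Side-chain hydrogen-bonding capability. Donors carry only N-H protons
    # (R guanidinium, K amine, W indole); acceptors carry only carbonyl
    # oxygens (D, E); 'both' side chains can donate and accept.
    "hbond_donor": frozenset("RKW"),
    "hbond_acceptor": frozenset("DE"),
    "hbond_both": frozenset("STYNQH"),
}


@dataclass(frozen=True)
class ResidueClassDefinitions:
    """Named, possibly overlapping residue sets used for binary tracks."""

    classes: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SETS))

    def __post_init__(self) -> None:
        for name, members in self.classes.items():
            bad = set(members) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"class {name!r} contains non-standard letters {sorted(bad)}")

    def get(self, name: str) -> frozenset:
        try:
            return frozenset(self.classes[name])
        except KeyError:
            raise KeyError(
                f"unknown residue class {name!r}; known: {sorted(self.classes)}"
            ) from None

    @classmethod
    def from_file(cls, path) -> "ResidueClassDefinitions":
        """Load class definitions from TSV: class_name <TAB> residue letters.

        Missing classes fall back to the defaults, so a file may override a
        single class.
        """
        classes = dict(DEFAULT_CLASS_SETS)
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"bad class-definition line: {line!r}")
            classes[parts[0]] = frozenset(parts[1].strip().upper())
        return cls(classes=classes)


@dataclass
class CompositionProfile:
    """Counts, frequencies (including X) and class fractions of a sequence."""

    counts: dict
    frequencies: dict
    class_fractions: dict


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (58.5 -> 59, -58.5 -> -59)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def aa_frequencies(
    s: SequenceRecord, defs: ResidueClassDefinitions | None = None
) -> CompositionProfile:
    """Composition profile of a sequence; frequencies sum to 1 over the
    20 standard letters plus X."""
    defs = defs or ResidueClassDefinitions()
    n = s.length
    letters = AMINO_ACIDS + "X"
    counts = {aa: s.residues.count(aa) for aa in letters}
    freqs = {aa: counts[aa] / n for aa in letters}
    fractions = {
        name: sum(counts[aa] for aa in members) / n
        for name, members in defs.classes.items()
    }
    return CompositionProfile(counts=counts, frequencies=freqs, class_fractions=fractions)


def class_track(
    s: SequenceRecord, class_name: str, defs: ResidueClassDefinitions | None = None
) -> FeatureTrack:
    """Binary per-residue track: 1 iff the residue belongs to the class."""
    defs = defs or ResidueClassDefinitions()
    members = defs.get(class_name)
    values = [1 if ch in members else 0 for ch in s.residues]
    return FeatureTrack(name=class_name, values=values, kind="binary")


def class_fraction(
    s: SequenceRecord, class_name: str, defs: ResidueClassDefinitions | None = None
) -> float:
    """Fraction of residues in the class (mean of the binary track)."""
    track = class_track(s, class_name, defs)
    return sum(track.values) / len(track)


def class_percent(
    s: SequenceRecord, class_name: str, defs: ResidueClassDefinitions | None = None
) -> int:
    """Class fraction as a whole percent (summary-style rounding)."""
    return round_half_away(100.0 * class_fraction(s, class_name, defs))


def load_reference_frequencies(path=None) -> dict:
    """Load a 20-row amino-acid background frequency table (TSV).

    Defaults to the shipped Swiss-Prot average composition. The frequencies
    must cover the 20 standard amino acids and sum to 1 within 1e-6.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "reference_frequencies.tsv"
    freqs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"bad reference-frequency line: {line!r}")
        aa, value = parts[0].strip().upper(), parts[1]
        try:
            freqs[aa] = float(value)
        except ValueError:
            raise FormatError(f"non-numeric frequency for {aa!r}: {value!r}") from None
    missing = set(AMINO_ACIDS) - set(freqs)
    if missing:
        raise FormatError(f"reference table missing amino acids {sorted(missing)}")
    total = sum(freqs[aa] for aa in AMINO_ACIDS)
    if abs(total - 1.0) > 1e-6:
        raise FormatError(f"reference frequencies sum to {total}, expected 1")
    return freqs


def enrichment_vs_reference(p: CompositionProfile, ref: dict) -> dict:
    """Per-amino-acid enrichment of a sequence against a background table.

    Returns {aa: (ratio, direction)} with direction in {enriched, depleted,
    neutral}; ratio is +inf when the background frequency is 0 but the query
    frequency is positive.
    """
    result = {}
    for aa in AMINO_ACIDS:
        fq = p.frequencies.get(aa, 0.0)
        fr = ref[aa]
        if fr == 0.0:
            ratio = math.inf if fq > 0 else 1.0
        else:
            ratio = fq / fr
        if ratio > 1.0:
            direction = "enriched"
        elif ratio < 1.0:
            direction = "depleted"
        else:
            direction = "neutral"
        result[aa] = (ratio, direction)
    return result
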