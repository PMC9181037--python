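"""Sequence and alignment IO, coordinate conventions, and core containers.

All coordinates in this package are 1-based inclusive, matching the way
protein regions are reported in the literature ("residues 164-267").
Sequences are validated to the 20 standard amino acids plus ``X``; the
ambiguity codes B/Z/J/U/O are mapped to ``X`` with a logged warning. ``X``
counts toward sequence length and fraction denominators but never matches a
physicochemical class or a motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters allowed in a validated residue string.
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: Ambiguity / non-standard codes folded into X.
_AMBIGUOUS = frozenset("BZJUO")


def _clean_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, strip whitespace/digits, fold ambiguity codes to X."""
    out = []
    n_ambiguous = 0
    for ch in raw.upper():
        if ch.isspace() or ch.isdigit():
            continue
        if ch in _AMBIGUOUS:
            n_ambiguous += 1
            ch = "X"
        if ch not in ALPHABET:
            raise FormatError(
                f"record {record_id!r}: illegal residue character {ch!r}"
            )
        out.append(ch)
    if n_ambiguous:
        logger.warning(
            "record %r: %d ambiguous residue(s) (B/Z/J/U/O) mapped to X",
            record_id, n_ambiguous,
        )
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein sequence with 1-based coordinates."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.id!r} has zero residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str = "") -> "SequenceRecord":
        return cls(id=id, residues=_clean_residues(raw, id), description=description)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval [{start}, {end}] outside 1..{self.length}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class Region:
    """A labeled 1-based inclusive interval on a sequence."""

    start: int
    end: int
    label: str = ""
    attributes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region", max_gap: int = 0) -> bool:
        """True if the intervals overlap or are separated by <= max_gap."""
        return self.start <= other.end + max_gap + 1 and other.start <= self.end + max_gap + 1


@dataclass
class FeatureTrack:
    """A per-residue feature vector aligned to a SequenceRecord.

    ``values`` is a sequence of length equal to the parent sequence: ints for
    binary tracks, floats for real-valued tracks, single-character strings for
    categorical tracks. Missing values are ``None`` (categorical) or NaN.
    """

    name: str
    values: list
    kind: str = "real"  # binary | categorical | real

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Alignment:
    """A parsed MSA with one distinguished query row.

    Gap characters are normalized to ``-``; rows are validated to equal length.
    """

    rows: list  # list of (id, gapped string)
    query_row_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows (lengths {sorted(lengths)})")
        ids = [rid for rid, _ in self.rows]
        if ids.count(self.query_row_id) != 1:
            raise KeyError(
                f"query row {self.query_row_id!r} matches "
                f"{ids.count(self.query_row_id)} rows (need exactly 1)"
            )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query_row(self) -> str:
        for rid, gapped in self.rows:
            if rid == self.query_row_id:
                return gapped
        raise KeyError(self.query_row_id)  # unreachable after validation

    def column(self, i: int) -> str:
        """Characters of 1-based column i, top to bottom."""
        if not (1 <= i <= self.n_columns):
            raise ValueError(f"column {i} outside 1..{self.n_columns}")
        return "".join(gapped[i - 1] for _, gapped in self.rows)


def read_fasta(path) -> list:
    """Read a (multi-)FASTA file into validated SequenceRecords."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord.from_raw(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


def _normalize_gapped(raw: str) -> str:
    """Uppercase and normalize gap characters {-, .} to '-'."""
    return raw.upper().replace(".", "-")


def read_alignment(path, query_id: str, format: str = "afa") -> Alignment:
    """Read an aligned-FASTA ('afa') or Stockholm MSA.

    Stockholm support is minimal and read-only: sequence rows are kept,
    per-column/per-file annotations are ignored (Biopython drops them for us).
    """
    fmt = {"afa": "fasta", "fasta": "fasta", "stockholm": "stockholm"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(Path(path)), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows = [(rec.id, _normalize_gapped(str(rec.seq))) for rec in msa]
    return Alignment(rows=rows, query_row_id=query_id)


def map_alignment_columns_to_query(a: Alignment) -> list:
    """Map each alignment column to a 1-based query position or None (gap).

    The mapping is strictly increasing over non-gap columns, so it is a
    bijection between non-gap query columns and 1..ungapped-query-length.
    """
    mapping = []
    pos = 0
    for ch in a.query_row:
        if ch == "-":
            mapping.append(None)
        else:
            pos += 1
            mapping.append(pos)
    return mapping


def load_fus_fixture() -> SequenceRecord:
    """The bundled canonical human FUS sequence (UniProt P35637, 526 aa)."""
    path = Path(__file__).parent / "data" / "fus_P35637.fasta"
    return read_fasta(path)[0]
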