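"""Per-column MSA conservation: strength (0-5), diversity (0-5), character.

* diversity bins the number of distinct amino acids observed in a column:
  1 -> 0, 2 -> 1, 3 -> 2, 4 -> 3, 5-6 -> 4, >= 7 -> 5 (0 = highly conserved,
  5 = poorly conserved). Gaps and X never count as amino acids.
* strength is a discretized column information content: IC = (log2 20 - H)
  scaled by column occupancy (the fraction of rows with a real residue),
  binned as floor(6 * IC / log2 20) and clipped to [0, 5]. A gap-free
  single-residue column scores 5, a uniform 20-residue column scores 0.
  This reproduces the hmmer-logo-style 0-5 contract without running HMMER;
  the scaling uses a flat background (an optional pseudocount softens empty
  categories but is off by default).
* character is the chemical class of the column's most common amino acid,
  resolved through a fixed precedence so overlapping class memberships give
  one answer: other(G, P) -> charge -> aromatic -> polar -> pi_system ->
  hydrophobic.

Columns with no amino-acid observations (all gap / all X) carry ``None``
sentinels rather than zeros.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .composition import ResidueClassDefinitions
from .seqio import AMINO_ACIDS, Alignment, map_alignment_columns_to_query

logger = logging.getLogger(__name__)

LOG2_20 = math.log2(20.0)

#: Order in which overlapping class memberships are resolved for character.
CHARACTER_PRECEDENCE = (
    ("other", frozenset("GP")),
    ("charge", None),      # filled from defs: positive | negative
    ("aromatic", None),
    ("polar", None),
    ("pi_system", None),
    ("hydrophobic", None),
)


@dataclass
class ConservationColumn:
    """Counts and derived conservation descriptors of one MSA column."""

    column_index: int  # 1-based
    counts: dict = field(default_factory=dict)
    gap_count: int = 0
    x_count: int = 0
    n_rows: int = 0
    information_bits: Optional[float] = None
    strength: Optional[int] = None
    diversity: Optional[int] = None
    character: Optional[str] = None

    @property
    def n_distinct(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    @property
    def n_observations(self) -> int:
        return sum(self.counts.values())


def column_counts(a: Alignment, i: int) -> ConservationColumn:
    """Residue counts of 1-based column i; gaps and X tallied separately."""
    chars = a.column(i)
    counts: Counter = Counter()
    gaps = x_count = 0
    for ch in chars:
        if ch == "-":
            gaps += 1
        elif ch == "X":
            x_count += 1
        elif ch in AMINO_ACIDS:
            counts[ch] += 1
        else:
            raise ValueError(f"column {i}: unexpected character {ch!r}")
    return ConservationColumn(
        column_index=i, counts=dict(counts), gap_count=gaps,
        x_count=x_count, n_rows=a.n_rows,
    )


def diversity_score(c: ConservationColumn) -> Optional[int]:
    """Bin n_distinct: 1->0, 2->1, 3->2, 4->3, 5 or 6->4, 7+->5; None if empty."""
    n = c.n_distinct
    if n == 0:
        return None
    if n <= 4:
        return n - 1
    if n <= 6:
        return 4
    return 5


def strength_score(
    c: ConservationColumn, pseudocount: float = 0.0
) -> tuple:
    """(information_bits, strength 0-5) of a column; (None, None) if empty.

    information_bits = (log2 20 - H) * occupancy, where H is the Shannon
    entropy of the column's amino-acid distribution and occupancy the
    fraction of rows carrying a real residue. ``pseudocount`` (in counts)
    is added to every amino-acid category before normalizing.
    """
    total = c.n_observations
    if total == 0:
        return None, None
    if pseudocount:
        probs = [
            (c.counts.get(aa, 0) + pseudocount) / (total + 20 * pseudocount)
            for aa in AMINO_ACIDS
        ]
    else:
        probs = [n / total for n in c.counts.values()]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    occupancy = total / c.n_rows if c.n_rows else 1.0
    info = max(0.0, (LOG2_20 - entropy) * occupancy)
    strength = min(5, max(0, math.floor(6.0 * info / LOG2_20)))
    return info, strength


def character_class(
    c: ConservationColumn, defs: Optional[ResidueClassDefinitions] = None
) -> Optional[str]:
    """Chemical class of the column's most common amino acid.

    Ties for the most common residue resolve to the alphabetically lowest
    letter (logged). Precedence handles overlapping memberships, e.g. G is
    'other' although it is also hydrophobic and a pi system; H is 'charge'
    although it is also aromatic.
    """
    if not c.counts:
        return None
    defs = defs or ResidueClassDefinitions()
    top = max(c.counts.values())
    winners = sorted(aa for aa, n in c.counts.items() if n == top)
    if len(winners) > 1:
        logger.info(
            "column %d: tie for most common residue %s; using %s",
            c.column_index, winners, winners[0],
        )
    aa = winners[0]
    lookup = {
        "other": frozenset("GP"),
        "charge": defs.get("positive") | defs.get("negative"),
        "aromatic": defs.get("aromatic"),
        "polar": defs.get("polar"),
        "pi_system": defs.get("pi_system"),
        "hydrophobic": defs.get("hydrophobic"),
    }
    for name, _ in CHARACTER_PRECEDENCE:
        if aa in lookup[name]:
            return name
    return "other"


def analyze_alignment(
    a: Alignment,
    defs: Optional[ResidueClassDefinitions] = None,
    pseudocount: float = 0.0,
) -> list:
    """All columns with counts and derived descriptors filled in."""
    columns = []
    for i in range(1, a.n_columns + 1):
        col = column_counts(a, i)
        col.information_bits, col.strength = strength_score(col, pseudocount)
        col.diversity = diversity_score(col)
        col.character = character_class(col, defs)
        columns.append(col)
    return columns


def project_to_query(a: Alignment, columns: Iterable[ConservationColumn]) -> list:
    """Conservation columns at non-gap query positions, in query order.

    Returns a list of length equal to the ungapped query; entry i-1 is the
    ConservationColumn aligned to query position i.
    """
    mapping = map_alignment_columns_to_query(a)
    by_index = {c.column_index: c for c in columns}
    track = []
    for col_idx, qpos in enumerate(mapping, start=1):
        if qpos is not None:
            track.append(by_index[col_idx])
    return track
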