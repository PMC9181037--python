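"""Regex-catalog motif scanning, GAR detection, and tandem n-mer repeats.

The scanner reports every overlapping match: after a hit at position p the
search restarts at p + 1, so two hits may share residues. GAR (glycine-
arginine-rich) regions are assembled from RGG/RG repeat-unit matches merged
over a configurable gap. LARKS and steric-zipper entries in the shipped
catalog are sequence proxies for structurally defined motifs (see the
catalog file header).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .errors import CatalogError
from .seqio import Region, SequenceRecord

MOTIF_CLASSES = {"GAR", "LARKS", "zipper", "custom"}


@dataclass(frozen=True)
class MotifCatalogEntry:
    name: str
    klass: str
    pattern: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.klass not in MOTIF_CLASSES:
            raise CatalogError(f"{self.name}: unknown motif class {self.klass!r}")
        if re.search(r"[a-z]", self.pattern):
            raise CatalogError(f"{self.name}: pattern must use uppercase residue letters")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise CatalogError(f"{self.name}: invalid pattern ({exc})") from exc

    @property
    def regex(self) -> "re.Pattern":
        return re.compile(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif match; 1-based inclusive, matched_text equals the slice."""

    start: int
    end: int
    name: str
    klass: str
    matched_text: str


def load_catalog(path=None) -> list:
    """Load a motif catalog TSV (name, class, pattern, source).

    Defaults to the shipped catalog. Pattern validity is checked here, at
    load time, so scanning never fails on a bad pattern.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "motif_catalog.tsv"
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise CatalogError(f"bad catalog line (need name/class/pattern): {line!r}")
        name, klass, pattern = parts[0], parts[1], parts[2]
        source = parts[3] if len(parts) > 3 else ""
        entries.append(MotifCatalogEntry(name=name, klass=klass, pattern=pattern, source=source))
    if not entries:
        raise CatalogError(f"{path}: empty motif catalog")
    return entries


def _scan_pattern(seq: str, compiled: "re.Pattern") -> list:
    """All overlapping matches of a pattern: (start0, end0_exclusive) pairs.

    Equivalent to attempting a match at every start position (the restart is
    at match start + 1, not match end).
    """
    hits = []
    pos = 0
    while pos <= len(seq):
        m = compiled.search(seq, pos)
        if m is None:
            break
        hits.append((m.start(), m.end()))
        pos = m.start() + 1
    return hits


def scan_catalog(s: SequenceRecord, catalog: Iterable[MotifCatalogEntry]) -> list:
    """Scan a sequence against a motif catalog; hits sorted by start, name."""
    catalog = list(catalog)
    if not catalog:
        raise ValueError("empty motif catalog")
    hits = []
    for entry in catalog:
        for start0, end0 in _scan_pattern(s.residues, entry.regex):
            if end0 == start0:  # ignore zero-length matches
                continue
            hits.append(
                MotifHit(
                    start=start0 + 1,
                    end=end0,
                    name=entry.name,
                    klass=entry.klass,
                    matched_text=s.residues[start0:end0],
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.name, h.end))


def _gar_patterns(spacer_max: int) -> list:
    unit_specs = [
        ("Tri-RGG", ["RGG"] * 3),
        ("Di-RGG", ["RGG"] * 2),
        ("Tri-RG", ["RG"] * 3),
        ("Di-RG", ["RG"] * 2),
    ]
    spacer = f".{{0,{spacer_max}}}"
    return [
        MotifCatalogEntry(name=name, klass="GAR", pattern=spacer.join(units),
                          source="RGG/RG repeat grammar")
        for name, units in unit_specs
    ]


def detect_gar(
    s: SequenceRecord, spacer_max: int = 4, merge_gap: int = 25
) -> list:
    """Glycine-arginine-rich regions from merged RGG/RG repeat hits.

    Di-/Tri-RGG and Di-/Tri-RG instances (repeat units separated by up to
    ``spacer_max`` arbitrary residues) are scanned with full overlap, then
    hits separated by at most ``merge_gap`` residues are unioned into GAR
    regions.
    """
    hits = scan_catalog(s, _gar_patterns(spacer_max))
    if not hits:
        return []
    intervals = sorted((h.start, h.end) for h in hits)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1] + merge_gap + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [
        Region(start=a, end=b, label="GAR", attributes=frozenset({"RGG/RG"}))
        for a, b in merged
    ]


def _is_periodic(unit: str) -> bool:
    """True if the unit is itself a repetition of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return True
    return False


def detect_tandem_repeats(
    s: SequenceRecord, k_max: int = 6, min_copies: int = 3
) -> list:
    """Maximal tandem repeats of k-mers (k <= k_max), minimal period.

    A region is reported when a k-mer occurs at least ``min_copies`` times
    consecutively, the unit is not itself periodic, and the run is maximal
    (not extendable by a full copy on either side). Partial trailing copies
    are not included in the region.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    seq = s.residues
    n = len(seq)
    regions = []
    seen = set()
    for k in range(1, k_max + 1):
        for i in range(0, n - k * min_copies + 1):
            unit = seq[i : i + k]
            if _is_periodic(unit):
                continue
            # maximality on the left: previous k residues must not repeat unit
            if i >= k and seq[i - k : i] == unit:
                continue
            copies = 1
            j = i + k
            while j + k <= n and seq[j : j + k] == unit:
                copies += 1
                j += k
            if copies < min_copies:
                continue
            key = (i + 1, i + k * copies, unit)
            if key in seen:
                continue
            seen.add(key)
            regions.append(
                Region(
                    start=i + 1,
                    end=i + k * copies,
                    label=f"repeat:{unit}x{copies}",
                    attributes=frozenset({unit}),
                )
            )
    # suppress rotated-phase duplicates: a run strictly contained in another
    # run of the same period is the same repeat seen off-phase
    def period(r: Region) -> int:
        return len(next(iter(r.attributes)))

    kept = [
        r for r in regions
        if not any(
            s is not r
            and period(s) == period(r)
            and s.start <= r.start
            and r.end <= s.end
            and s.length > r.length
            for s in regions
        )
    ]
    return sorted(kept, key=lambda r: (r.start, r.end, r.label))
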