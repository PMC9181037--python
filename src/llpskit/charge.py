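"""Charge tracks and charge-decoration scalars (FCR, NCPR, OCS, SCD, CIDER).

Two charge conventions are exposed:

* ``patterning`` — display convention: +1 for {H, K, R}, -1 for {E, D}. This
  is the set used for binary charge-distribution tracks, where histidine is
  grouped with the positives.
* ``decoration`` — metric convention (default): +1 for {K, R}, -1 for {D, E}.
  Histidine is excluded, as in the CIDER framework of Das & Pappu, so that
  FCR/NCPR/OCS/SCD and the diagram classification are comparable with the
  published charge-decoration literature.

Scalars (N = sequence length, f+ / f- = fractions of positive / negative
residues):

* FCR  = f+ + f-
* NCPR = f+ - f-
* OCS  = (f+ - f-)^2 / (f+ + f-), defined as 0 when FCR = 0
* SCD  = (1/N) * sum_{m>n} q_m q_n sqrt(m - n)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seqio import FeatureTrack, Region, SequenceRecord

CONVENTIONS = {
    "patterning": (frozenset("HKR"), frozenset("ED")),
    "decoration": (frozenset("KR"), frozenset("DE")),
}

CIDER_CLASSES = (
    "weak polyampholyte/polyelectrolyte",
    "Janus",
    "strong polyampholyte",
    "strong negative polyelectrolyte",
    "strong positive polyelectrolyte",
)


@dataclass
class ChargeVector:
    """Per-residue charges in {-1, 0, +1} plus the residue sets used."""

    q: np.ndarray
    positive_set: frozenset
    negative_set: frozenset

    def __len__(self) -> int:
        return self.q.size


@dataclass
class ChargeDecoration:
    """Whole-sequence (or segment) charge-decoration scalars."""

    f_plus: float
    f_minus: float
    fcr: float
    ncpr: float
    ocs: float
    scd: float
    cider_class: str


def charge_vector(s: SequenceRecord, convention: str = "decoration") -> ChargeVector:
    try:
        positive, negative = CONVENTIONS[convention]
    except KeyError:
        raise KeyError(
            f"unknown charge convention {convention!r}; known: {sorted(CONVENTIONS)}"
        ) from None
    q = np.zeros(s.length, dtype=np.int8)
    for i, ch in enumerate(s.residues):
        if ch in positive:
            q[i] = 1
        elif ch in negative:
            q[i] = -1
    return ChargeVector(q=q, positive_set=positive, negative_set=negative)


def fcr(v: ChargeVector) -> float:
    """Fraction of charged residues: f+ + f-."""
    return float(np.count_nonzero(v.q)) / len(v)


def ncpr(v: ChargeVector, region: Optional[Region] = None) -> float:
    """Net charge per residue of the full sequence or a 1-based region."""
    q = v.q
    if region is not None:
        if region.end > len(v):
            raise ValueError(f"region [{region.start}, {region.end}] outside sequence")
        q = q[region.start - 1 : region.end]
    if q.size == 0:
        raise ValueError("empty region")
    return float(q.sum()) / q.size


def _fractions(v: ChargeVector) -> tuple:
    n = len(v)
    return float((v.q == 1).sum()) / n, float((v.q == -1).sum()) / n


def ocs(v: ChargeVector) -> float:
    """Overall charge symmetry (f+ - f-)^2 / (f+ + f-); 0 for a chargeless
    sequence (the continuous limit of the 0/0 form)."""
    f_plus, f_minus = _fractions(v)
    total = f_plus + f_minus
    if total == 0.0:
        return 0.0
    return (f_plus - f_minus) ** 2 / total


def scd(v: ChargeVector) -> float:
    """Sequence charge decoration: distance-weighted pairwise charge sum.

    Evaluated over charged positions only, which is algebraically identical
    to the naive double loop over all residue pairs (neutral residues
    contribute zero terms).
    """
    idx = np.flatnonzero(v.q)
    if idx.size < 2:
        return 0.0
    q = v.q[idx].astype(np.float64)
    pos = idx.astype(np.float64)  # 0-based; pair separations are unaffected
    sep = pos[:, None] - pos[None, :]
    weights = np.sqrt(np.abs(sep))
    total = q @ weights @ q  # sums every ordered pair; diagonal is 0
    return float(total / 2.0 / len(v))


def classify_cider(f_plus: float, f_minus: float) -> str:
    """Das-Pappu diagram region from the positive/negative charge fractions.

    Boundaries: FCR < 0.25 -> weak polyampholyte/polyelectrolyte;
    0.25 <= FCR <= 0.35 -> Janus (boundary) region; FCR > 0.35 splits into a
    strong polyelectrolyte when one sign dominates (that fraction > 0.35 and
    the other <= 0.35) and a strong polyampholyte otherwise.
    """
    if not (0.0 <= f_plus <= 1.0 and 0.0 <= f_minus <= 1.0):
        raise ValueError("charge fractions must lie in [0, 1]")
    total = f_plus + f_minus
    if total < 0.25:
        return CIDER_CLASSES[0]
    if total <= 0.35:
        return CIDER_CLASSES[1]
    if f_plus > 0.35 and f_minus <= 0.35:
        return CIDER_CLASSES[4]
    if f_minus > 0.35 and f_plus <= 0.35:
        return CIDER_CLASSES[3]
    return CIDER_CLASSES[2]


def charge_decoration(
    s: SequenceRecord,
    convention: str = "decoration",
    region: Optional[Region] = None,
) -> ChargeDecoration:
    """All decoration scalars for a sequence (or a segment of it)."""
    if region is not None:
        s = SequenceRecord(id=f"{s.id}:{region.start}-{region.end}",
                           residues=s.slice(region.start, region.end))
    v = charge_vector(s, convention)
    f_plus, f_minus = _fractions(v)
    return ChargeDecoration(
        f_plus=f_plus,
        f_minus=f_minus,
        fcr=f_plus + f_minus,
        ncpr=f_plus - f_minus,
        ocs=ocs(v),
        scd=scd(v),
        cider_class=classify_cider(f_plus, f_minus),
    )


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Per-residue mean over a centered window clipped at the termini."""
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    left, right = (window - 1) // 2, window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def ncpr_track(v: ChargeVector, window: int = 10) -> FeatureTrack:
    """Sliding net charge per residue (centered window, clipped at termini)."""
    values = _sliding_mean(v.q.astype(np.float64), window)
    return FeatureTrack(name=f"ncpr_w{window}", values=values.tolist(), kind="real")


def fcr_track(v: ChargeVector, window: int = 10) -> FeatureTrack:
    """Sliding fraction of charged residues."""
    values = _sliding_mean(np.abs(v.q).astype(np.float64), window)
    return FeatureTrack(name=f"fcr_w{window}", values=values.tolist(), kind="real")
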