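"""Seeded synthetic sequence and predictor-track generators for testing.

These generators emulate the *shape* of real inputs — residue alphabets,
track dialects, probability ranges — not their biology: uniform or
composition-biased residue draws carry none of the positional correlation,
domain structure, or evolutionary signal of real proteins. They exist so the
statistics in this package can be exercised against inputs with known,
constructed properties (embedded homopolymer blocks, prescribed biases).
"""

from __future__ import annotations

import numpy as np

from .seqio import AMINO_ACIDS, SequenceRecord
from .consensus import PredictionTrack


def random_sequence(
    length: int,
    rng: np.random.Generator,
    frequencies: dict | None = None,
    id: str = "synthetic",
) -> SequenceRecord:
    """A random sequence: uniform over the 20 standard residues, or drawn
    from the given composition (need not be normalized)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = list(AMINO_ACIDS)
    if frequencies is None:
        probs = None
    else:
        weights = np.array([frequencies.get(aa, 0.0) for aa in letters], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("frequencies must have positive mass")
        probs = weights / weights.sum()
    residues = "".join(rng.choice(letters, size=length, p=probs))
    return SequenceRecord(id=id, residues=residues)


def embed_block(
    context_length: int,
    block: str,
    rng: np.random.Generator,
    id: str = "synthetic-embedded",
) -> tuple:
    """A uniform-random sequence with ``block`` inserted at a random offset.

    Returns (record, 1-based start of the block).
    """
    context = random_sequence(context_length, rng).residues
    offset = int(rng.integers(0, context_length - len(block) + 1))
    residues = context[:offset] + block + context[offset + len(block):]
    return SequenceRecord(id=id, residues=residues), offset + 1


def random_disorder_tracks(
    length: int, n_sources: int, rng: np.random.Generator
) -> list:
    """Independent uniform disorder-probability tracks from fake predictors."""
    return [
        PredictionTrack(
            source=f"tool{k}", feature="disorder_prob",
            values=rng.random(length),
        )
        for k in range(n_sources)
    ]


def random_categorical_tracks(
    length: int, n_sources: int, states: str, feature: str,
    rng: np.random.Generator,
) -> list:
    """Independent uniform categorical tracks (e.g. ss3 votes)."""
    return [
        PredictionTrack(
            source=f"tool{k}", feature=feature,
            values="".join(rng.choice(list(states), size=length)),
        )
        for k in range(n_sources)
    ]
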