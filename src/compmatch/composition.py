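"""Amino-acid counting, percent-composition vectors, and compositional identity.

Compositional identity (CI) quantifies how similar two sequences are in bulk
amino-acid composition, irrespective of residue order:

    CI = 100 - D_manhattan(q, s) / 2

where ``D_manhattan`` is the Manhattan (L1) distance between the two
20-dimensional percent-composition vectors over the canonical amino acids.
CI is 100 when the compositions are identical (e.g. a sequence versus any
permutation of itself) and 0 when they share no residues at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Canonical amino acids, alphabetical by one-letter code. All composition
#: vectors and count arrays are ordered by this string.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(CANONICAL_AA)}

N_AA = len(CANONICAL_AA)

# 256-entry lookup: byte value of residue -> index in CANONICAL_AA, or N_AA
# for anything non-canonical (X, B, Z, U, O, J, ...).
_BYTE_TO_INDEX = np.full(256, N_AA, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _BYTE_TO_INDEX[ord(_aa)] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an uppercase sequence to canonical-alphabet indices.

    Returns a uint8 array of length ``len(sequence)`` where canonical
    residues map to their index in :data:`CANONICAL_AA` and every other
    character maps to ``N_AA`` (the non-canonical bin).
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BYTE_TO_INDEX[raw]


@dataclass(frozen=True)
class ResidueCounts:
    """Integer residue tallies for one sequence window.

    ``counts[i]`` is the tally of ``CANONICAL_AA[i]``; residues outside the
    canonical alphabet accumulate in ``noncanonical``. The invariant
    ``counts.sum() + noncanonical == length`` always holds.
    """

    counts: np.ndarray
    noncanonical: int
    length: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) + self.noncanonical != self.length:
            raise ValueError("residue counts do not sum to window length")

    def as_dict(self) -> dict[str, int]:
        return {aa: int(self.counts[i]) for i, aa in enumerate(CANONICAL_AA)}

    def slide(self, leaving: str, entering: str) -> "ResidueCounts":
        """Counts for the window shifted right by one residue.

        ``leaving`` is the residue dropped at the left edge, ``entering`` the
        residue gained at the right edge. Equivalent to recounting the
        shifted window from scratch. Removing a residue that is not present
        signals an inconsistent caller and raises ``ValueError``.
        """
        counts = self.counts.copy()
        noncanonical = self.noncanonical
        i = AA_INDEX.get(leaving)
        if i is None:
            if noncanonical < 1:
                raise ValueError("slide underflow: no non-canonical residue to remove")
            noncanonical -= 1
        else:
            if counts[i] < 1:
                raise ValueError(f"slide underflow: no {leaving!r} in window")
            counts[i] -= 1
        j = AA_INDEX.get(entering)
        if j is None:
            noncanonical += 1
        else:
            counts[j] += 1
        return ResidueCounts(counts, noncanonical, self.length)


def count_residues(sequence: str) -> ResidueCounts:
    """Exact residue tallies for an uppercase amino-acid string."""
    if not sequence:
        raise ValueError("cannot count residues of an empty sequence")
    idx = encode_sequence(sequence)
    tallies = np.bincount(idx, minlength=N_AA + 1)
    return ResidueCounts(
        counts=tallies[:N_AA].astype(np.int64),
        noncanonical=int(tallies[N_AA]),
        length=len(sequence),
    )


def slide_counts(counts: ResidueCounts, leaving: str, entering: str) -> ResidueCounts:
    """Functional alias for :meth:`ResidueCounts.slide`."""
    return counts.slide(leaving, entering)


@dataclass(frozen=True)
class CompositionVector:
    """Percent composition over the 20 canonical amino acids.

    ``percent[i]`` is the percentage of residue ``CANONICAL_AA[i]`` in the
    source window; ``length`` is the number of residues the vector was
    computed over. Percents sum to 100 exactly when the source window
    contains only canonical residues; non-canonical residues dilute the sum
    below 100 (they count toward ``length`` but toward no canonical bin).
    """

    percent: np.ndarray = field(repr=False)
    length: int

    def __post_init__(self) -> None:
        if self.percent.shape != (N_AA,):
            raise ValueError(f"percent vector must have {N_AA} entries")
        if np.any(self.percent < 0) or np.any(self.percent > 100):
            raise ValueError("percent values must lie in [0, 100]")
        if self.length < 1:
            raise ValueError("composition length must be positive")

    def __getitem__(self, aa: str) -> float:
        return float(self.percent[AA_INDEX[aa]])

    def as_dict(self) -> dict[str, float]:
        return {aa: float(self.percent[i]) for i, aa in enumerate(CANONICAL_AA)}

    @classmethod
    def from_sequence(cls, sequence: str) -> "CompositionVector":
        return percent_composition(count_residues(sequence))

    @classmethod
    def from_percents(
        cls, percents: Mapping[str, float], length: int = 100
    ) -> "CompositionVector":
        """Build a vector from an explicit ``{residue: percent}`` mapping.

        Unlisted canonical residues default to 0. ``length`` is a nominal
        window size for vectors that are specified rather than measured
        (e.g. generator backgrounds and planting targets).
        """
        vec = np.zeros(N_AA)
        for aa, pct in percents.items():
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino acid {aa!r}")
            vec[AA_INDEX[aa]] = float(pct)
        return cls(percent=vec, length=length)


def percent_composition(counts: ResidueCounts) -> CompositionVector:
    """Convert integer tallies to a percent-composition vector."""
    if counts.length < 1:
        raise ValueError("cannot compute composition over zero residues")
    percent = counts.counts * 100.0 / counts.length
    return CompositionVector(percent=percent, length=counts.length)


def manhattan_distance(q: CompositionVector, s: CompositionVector) -> float:
    """L1 distance between two composition vectors; symmetric, in [0, 200]."""
    return float(np.abs(q.percent - s.percent).sum())


def euclidean_distance(q: CompositionVector, s: CompositionVector) -> float:
    """L2 distance between two composition vectors; symmetric."""
    return math.sqrt(float(((q.percent - s.percent) ** 2).sum()))


def compositional_identity(q: CompositionVector, s: CompositionVector) -> float:
    """CI = 100 - Manhattan distance / 2, in [0, 100].

    100 exactly when the two compositions are identical; 0 when the two
    windows share no canonical residues.
    """
    return 100.0 - manhattan_distance(q, s) / 2.0
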