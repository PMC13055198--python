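"""All-vs-all comparison: compositional identity versus alignment identity.

The point of laying CI and global-alignment percent identity side by side
is to show that compositionally near-identical regions need not share any
primary-sequence homology: a sequence and its shuffle score CI = 100 while
their alignment identity is generically far below 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .composition import CompositionVector, compositional_identity
from .fasta import ProteinRecord


@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scoring scheme with affine gaps.

    Defaults mirror the common global-alignment defaults used for percent
    identity: BLOSUM62, gap open 10, gap extend 0.5, end gaps free.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_penalized: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    if not scoring.end_gaps_penalized:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


def global_alignment_identity(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = 100 * identical aligned columns / total alignment columns,
    gap columns included in the denominator. When several alignments are
    co-optimal the aligner's first alignment is used, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scoring)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        raise ValueError(f"residues absent from {scoring.matrix}: {sorted(bad)}")
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric CI and alignment-identity matrices over labeled sequences.

    Both layers are full symmetric matrices with 100 on the diagonal; when
    rendered as one heatmap the convention is CI in the upper triangle and
    primary-sequence identity in the lower triangle.
    """

    labels: tuple[str, ...]
    ci: np.ndarray
    identity: np.ndarray


def pairwise_matrix(
    seqs: Sequence[ProteinRecord | tuple[str, str]],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseMatrix:
    """All-vs-all CI and global-alignment identity for >= 2 sequences.

    CI is computed from full-sequence compositions; identity from global
    alignment under ``scoring``. Both matrices are symmetric by
    construction.
    """
    pairs = [
        (s.id, s.sequence) if isinstance(s, ProteinRecord) else (s[0], s[1])
        for s in seqs
    ]
    if len(pairs) < 2:
        raise ValueError("pairwise comparison needs at least 2 sequences")
    labels = tuple(label for label, _ in pairs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")

    n = len(pairs)
    comps = [CompositionVector.from_sequence(seq) for _, seq in pairs]
    ci = np.full((n, n), 100.0)
    identity = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ci[i, j] = ci[j, i] = compositional_identity(comps[i], comps[j])
            pid = global_alignment_identity(pairs[i][1], pairs[j][1], scoring)
            identity[i, j] = identity[j, i] = pid
    return PairwiseMatrix(labels=labels, ci=ci, identity=identity)
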