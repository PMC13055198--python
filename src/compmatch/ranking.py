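"""Proteome-wide ranking of per-protein best regions and rank comparisons.

Also houses the prominent-feature annotation (amino acids exceeding a
display threshold in either the query or the matched region) and the two
rank-robustness operations: the percentile of a reference hit within
another ranking, and the signed rank difference of one hit between two
rankings (e.g. Manhattan- versus Euclidean-ranked searches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .composition import CANONICAL_AA, CompositionVector
from .scan import MatchRegion, SearchParams


@dataclass(frozen=True)
class SearchResult:
    """Ranked output of one proteome scan.

    ``matches`` is sorted by the ranking key; the rank of ``matches[i]`` is
    ``i + 1``. ``skipped`` lists (protein_id, reason) pairs for proteins
    that produced no window.
    """

    query_id: str
    params: SearchParams
    matches: tuple[MatchRegion, ...]
    skipped: tuple[tuple[str, str], ...] = ()
    query_composition: Optional[CompositionVector] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.matches)

    def rank_of(self, protein_id: str) -> int:
        """1-based rank of a protein in this result."""
        for i, m in enumerate(self.matches):
            if m.protein_id == protein_id:
                return i + 1
        raise KeyError(f"protein {protein_id!r} not in ranked matches")

    def top(self, n: int) -> "SearchResult":
        """The first ``n`` ranks (prefix of the full ranking)."""
        return SearchResult(
            self.query_id,
            self.params,
            self.matches[:n],
            self.skipped,
            self.query_composition,
        )


def rank_matches(
    regions: Sequence[MatchRegion],
    metric: str = "manhattan",
    *,
    query_id: str = "query",
    query_composition: Optional[CompositionVector] = None,
    params: Optional[SearchParams] = None,
    skipped: Sequence[tuple[str, str]] = (),
) -> SearchResult:
    """Sort per-protein best regions into a dense 1..N ranking.

    Manhattan metric ranks by descending CI; Euclidean ranks by ascending
    raw distance. Ties are broken by protein id, ascending lexicographically,
    so rankings are reproducible across runs and platforms.
    """
    ids = [r.protein_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids among regions")
    if metric == "manhattan":
        key = lambda r: (-r.ci, r.protein_id)
    else:
        key = lambda r: (r.distance, r.protein_id)
    ordered = tuple(sorted(regions, key=key))
    if params is None:
        params = SearchParams(metric=metric) if metric in ("manhattan", "euclidean") else SearchParams()
    return SearchResult(
        query_id=query_id,
        params=params,
        matches=ordered,
        skipped=tuple(skipped),
        query_composition=query_composition,
    )


def prominent_features(
    query_comp: CompositionVector,
    subject_comp: CompositionVector,
    threshold_percent: float = 10.0,
) -> set[str]:
    """Amino acids strictly exceeding the threshold in either composition.

    These are the residues worth displaying when eyeballing a match: the
    dominant compositional features of the query and/or the matched region.
    The comparison is strict (exactly 10.0% is excluded).
    """
    return {
        aa
        for aa in CANONICAL_AA
        if query_comp[aa] > threshold_percent or subject_comp[aa] > threshold_percent
    }


def rank_percentile(reference_hit: str, other: SearchResult) -> float:
    """Percentile of a reference hit within another ranking.

    ``100 * (N - rank + 1) / N`` with N the number of ranked matches: the
    top hit of a search evaluated against its own ranking scores exactly
    100, and the bottom hit scores 100/N.
    """
    rank = other.rank_of(reference_hit)
    n = len(other.matches)
    return 100.0 * (n - rank + 1) / n


def rank_difference(hit: str, result_a: SearchResult, result_b: SearchResult) -> int:
    """Signed rank change of one hit between two rankings (b minus a)."""
    return result_b.rank_of(hit) - result_a.rank_of(hit)
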