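"""Sliding-window proteome scan.

For every window size in ``[min_window, max_window]`` and every start
position, the window's percent composition is compared to the query
composition under the selected distance metric, and the single best window
per protein is kept. The scan uses prefix-sum residue counts so each window
size costs O(L) per protein rather than O(L * w).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .composition import (
    N_AA,
    CompositionVector,
    count_residues,
    encode_sequence,
    percent_composition,
)
from .fasta import ProteinRecord

METRICS = ("manhattan", "euclidean")


@dataclass(frozen=True)
class SearchParams:
    """Search configuration.

    Defaults (window range 90-120 inclusive, Manhattan metric) target
    IDR/PrLD-scale domains: windows of roughly one functional disordered
    region. ``strict_noncanonical`` discards any window containing a
    non-canonical residue; by default such residues merely dilute the
    canonical composition of their window.
    """

    min_window: int = 90
    max_window: int = 120
    metric: str = "manhattan"
    strict_noncanonical: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_window <= self.max_window):
            raise ValueError("window sizes must satisfy 1 <= min_window <= max_window")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")

    def window_sizes(self) -> range:
        return range(self.min_window, self.max_window + 1)


@dataclass(frozen=True)
class MatchRegion:
    """Best-scoring window of one protein.

    Coordinates are 1-based inclusive. ``distance`` is the value of the
    metric the search ranked by; ``ci`` is always the Manhattan-based
    compositional identity of the window against the query, regardless of
    the ranking metric.
    """

    protein_id: str
    start: int
    end: int
    window_length: int
    distance: float
    ci: float
    subsequence: str


def n_windows(length: int, params: SearchParams) -> int:
    """Number of windows evaluated for a protein of the given length."""
    return sum(max(0, length - w + 1) for w in params.window_sizes())


def _window_distances(
    prefix: np.ndarray, w: int, query_percent: np.ndarray, metric: str
) -> np.ndarray:
    """Distance of every length-``w`` window to the query composition.

    ``prefix`` is the (L+1, N_AA+1) cumulative count matrix; the last column
    tallies non-canonical residues. Returns (distances, n_noncanonical).
    """
    counts = prefix[w:, :N_AA] - prefix[:-w, :N_AA]
    percents = counts * 100.0 / w
    diff = percents - query_percent
    if metric == "manhattan":
        dist = np.abs(diff).sum(axis=1)
    else:
        dist = np.sqrt((diff * diff).sum(axis=1))
    return dist


def scan_protein(
    protein: ProteinRecord,
    query_comp: CompositionVector,
    params: SearchParams,
) -> Optional[MatchRegion]:
    """Best window of one protein, or None if the protein is too short.

    Ties are broken deterministically: smallest distance, then leftmost
    start, then largest window size. In strict non-canonical mode a protein
    with no clean window also returns None.
    """
    seq = protein.sequence
    L = len(seq)
    if L < params.min_window:
        return None

    idx = encode_sequence(seq)
    onehot = np.zeros((L, N_AA + 1), dtype=np.int32)
    onehot[np.arange(L), idx] = 1
    prefix = np.zeros((L + 1, N_AA + 1), dtype=np.int32)
    np.cumsum(onehot, axis=0, out=prefix[1:])

    qp = query_comp.percent
    best_key: tuple[float, int, int] | None = None
    for w in params.window_sizes():
        if w > L:
            break
        dist = _window_distances(prefix, w, qp, params.metric)
        if params.strict_noncanonical:
            nc = prefix[w:, N_AA] - prefix[:-w, N_AA]
            dist = np.where(nc > 0, np.inf, dist)
            if not np.isfinite(dist).any():
                continue
        i = int(np.argmin(dist))  # argmin returns the leftmost minimum
        key = (float(dist[i]), i, -w)
        if best_key is None or key < best_key:
            best_key = key
    if best_key is None:
        return None

    d, start0, neg_w = best_key
    w = -neg_w
    window_seq = seq[start0 : start0 + w]
    window_comp = percent_composition(count_residues(window_seq))
    ci = 100.0 - float(np.abs(qp - window_comp.percent).sum()) / 2.0
    return MatchRegion(
        protein_id=protein.id,
        start=start0 + 1,
        end=start0 + w,
        window_length=w,
        distance=d,
        ci=ci,
        subsequence=window_seq,
    )


def scan_proteome(
    proteome: Sequence[ProteinRecord],
    query: ProteinRecord | str,
    params: SearchParams = SearchParams(),
):
    """Scan every protein against the query composition and rank the hits.

    The query composition is computed once over the full query sequence as
    given, even when the query length lies outside the window range.
    Proteins shorter than ``min_window`` (or, in strict mode, with no
    window free of non-canonical residues) are recorded in the skip log.
    Returns a ranked :class:`~compmatch.ranking.SearchResult`.
    """
    from .ranking import rank_matches

    if not proteome:
        raise ValueError("proteome is empty")
    if isinstance(query, str):
        query = ProteinRecord("query", "", query)
    counts = count_residues(query.sequence)
    if int(counts.counts.sum()) == 0:
        raise ValueError("query contains no canonical residues")
    query_comp = percent_composition(counts)

    regions: list[MatchRegion] = []
    skipped: list[tuple[str, str]] = []
    for protein in proteome:
        region = scan_protein(protein, query_comp, params)
        if region is not None:
            regions.append(region)
        elif len(protein) < params.min_window:
            skipped.append((protein.id, f"shorter than min_window ({params.min_window})"))
        else:
            skipped.append((protein.id, "no window free of non-canonical residues"))
    return rank_matches(
        regions,
        params.metric,
        query_id=query.id,
        query_composition=query_comp,
        params=params,
        skipped=skipped,
    )
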