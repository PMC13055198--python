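"""Sliding-window scan: oracle equivalence, tie rules, determinism."""

import numpy as np
import pytest

from compmatch import (
    CANONICAL_AA,
    CompositionVector,
    ProteinRecord,
    SearchParams,
    n_windows,
    scan_protein,
    scan_proteome,
)
from oracle_utils import brute_force_best

POLY_A = CompositionVector.from_percents({"A": 100})


class TestScanProtein:
    def test_finds_planted_window(self):
        protein = ProteinRecord("p", "", "GGGGAAAAGGGG")
        region = scan_protein(protein, POLY_A, SearchParams(4, 4))
        assert (region.start, region.end, region.ci) == (5, 8, 100.0)
        assert region.subsequence == "AAAA"

    def test_short_protein_is_absent(self):
        protein = ProteinRecord("p", "", "A" * 50)
        assert scan_protein(protein, POLY_A, SearchParams(90, 120)) is None

    def test_tie_breaks_leftmost(self):
        """All windows of AGAGAGAG tie at CI 100; leftmost start wins."""
        protein = ProteinRecord("p", "", "AGAGAGAG")
        query = CompositionVector.from_percents({"A": 50, "G": 50})
        region = scan_protein(protein, query, SearchParams(4, 4))
        assert (region.start, region.end) == (1, 4)

    def test_tie_breaks_largest_window(self):
        """Same distance and start across window sizes: largest window wins."""
        protein = ProteinRecord("p", "", "AAAA")
        region = scan_protein(protein, POLY_A, SearchParams(2, 4))
        assert (region.start, region.end, region.window_length) == (1, 4, 4)

    def test_strict_mode_skips_contaminated_windows(self):
        protein = ProteinRecord("p", "", "AAXAAAAA")
        region = scan_protein(
            protein, POLY_A, SearchParams(4, 4, strict_noncanonical=True)
        )
        assert region.start == 4 and "X" not in region.subsequence

    def test_strict_mode_all_windows_contaminated(self):
        protein = ProteinRecord("p", "", "AXAXAXAX")
        assert (
            scan_protein(protein, POLY_A, SearchParams(4, 4, strict_noncanonical=True))
            is None
        )

    def test_euclidean_ranking_keeps_manhattan_ci(self):
        protein = ProteinRecord("p", "", "GGGGAAAAGGGG")
        region = scan_protein(protein, POLY_A, SearchParams(4, 4, metric="euclidean"))
        assert region.ci == 100.0 and region.distance == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
    @pytest.mark.parametrize("strict", [False, True])
    def test_scan_equals_exhaustive_search(self, rng, metric, strict):
        """The prefix-sum scan must agree exactly, including float ties,
        with a from-scratch recount of every window."""
        alphabet = list(CANONICAL_AA + "X")
        weights = [0.049] * 20 + [0.02]
        for trial in range(12):
            L = int(rng.integers(20, 300))
            seq = "".join(rng.choice(alphabet, size=L, p=weights))
            mn = int(rng.integers(3, 30))
            mx = mn + int(rng.integers(0, 40))
            params = SearchParams(mn, mx, metric, strict_noncanonical=strict)
            query = "".join(rng.choice(list(CANONICAL_AA), size=60))
            qcomp = CompositionVector.from_sequence(query)
            region = scan_protein(ProteinRecord("p", "", seq), qcomp, params)
            expected = None
            if L >= mn:
                expected = brute_force_best(seq, qcomp.percent, mn, mx, metric, strict)
            if expected is None:
                assert region is None
            else:
                d, s0, w = expected
                assert region is not None
                assert (region.distance, region.start - 1, region.window_length) == (
                    d,
                    s0,
                    w,
                )


class TestWindowCounting:
    @pytest.mark.parametrize(
        "length,mn,mx",
        [(100, 90, 120), (50, 90, 120), (300, 10, 40), (10, 1, 10)],
    )
    def test_window_count_formula(self, length, mn, mx):
        params = SearchParams(mn, mx)
        enumerated = sum(
            1
            for w in range(mn, mx + 1)
            for _ in range(max(0, length - w + 1))
        )
        assert n_windows(length, params) == enumerated


class TestScanProteome:
    def test_self_match_ranks_first(self, small_proteome):
        # window range spans the query's length: its own full-length window
        # matches the query composition exactly
        query = small_proteome[3]
        params = SearchParams(30, 200)
        result = scan_proteome(small_proteome, query, params)
        assert result.matches[0].protein_id == query.id
        assert result.matches[0].ci == 100.0

    def test_short_proteins_logged_not_ranked(self, small_proteome):
        proteome = small_proteome + [ProteinRecord("tiny", "", "MKV")]
        result = scan_proteome(proteome, small_proteome[0], SearchParams(30, 60))
        assert ("tiny", "shorter than min_window (30)") in result.skipped
        assert all(m.protein_id != "tiny" for m in result.matches)

    def test_order_independence(self, small_proteome, rng):
        """Ranking is identical whatever the input record order."""
        query = small_proteome[0].sequence
        params = SearchParams(30, 60)
        a = scan_proteome(small_proteome, query, params)
        shuffled = [small_proteome[i] for i in rng.permutation(len(small_proteome))]
        b = scan_proteome(shuffled, query, params)
        assert a.matches == b.matches

    def test_monotone_window_range_bound(self, small_proteome):
        """Best CI over a window range dominates any subrange."""
        query = small_proteome[0].sequence
        wide = scan_proteome(small_proteome, query, SearchParams(30, 70))
        narrow = scan_proteome(small_proteome, query, SearchParams(40, 60))
        assert wide.matches[0].ci >= narrow.matches[0].ci

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            scan_proteome([], "ACDEF", SearchParams(2, 3))

    def test_noncanonical_query_rejected(self, small_proteome):
        with pytest.raises(ValueError):
            scan_proteome(small_proteome, "XXXX", SearchParams(2, 3))
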