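"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the scan oracle
recounts every window from scratch, and the alignment oracle enumerates
every global alignment of two short sequences under affine gap scoring.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_IDX = {aa: i for i, aa in enumerate(_ALPHABET)}


def brute_force_best(seq, query_percent, min_window, max_window,
                     metric="manhattan", strict_noncanonical=False):
    """Exhaustive from-scratch search: recount and score every window.

    Returns (distance, start0, window) of the best window under the
    tie-break order (smallest distance, leftmost start, largest window),
    or None when no window is eligible.
    """
    best = None
    for w in range(min_window, max_window + 1):
        for s0 in range(0, len(seq) - w + 1):
            window = seq[s0:s0 + w]
            counts = np.zeros(20)
            noncanonical = 0
            for ch in window:
                i = _IDX.get(ch)
                if i is None:
                    noncanonical += 1
                else:
                    counts[i] += 1
            if strict_noncanonical and noncanonical > 0:
                continue
            diff = counts * 100.0 / w - query_percent
            if metric == "manhattan":
                d = float(np.abs(diff).sum())
            else:
                d = float(np.sqrt((diff * diff).sum()))
            key = (d, s0, -w)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    d, s0, neg_w = best
    return d, s0, -neg_w


def enumerate_global_alignments(a, b, gap_open=10.0, gap_extend=0.5,
                                end_gaps_free=True, matrix_name="BLOSUM62"):
    """Enumerate every global alignment of two short sequences.

    Affine scoring: a gap run of length k costs open + (k - 1) * extend;
    end gaps are free when ``end_gaps_free``. Returns a dict mapping each
    achievable score to the set of percent identities (identical columns
    over total columns) realized at that score. Exponential -- keep the
    sequences short.
    """
    matrix = substitution_matrices.load(matrix_name)
    results: dict[float, set[float]] = {}

    def rec(i, j, n_cols, n_ident, score, last):
        if i == len(a) and j == len(b):
            pid = 100.0 * n_ident / n_cols
            results.setdefault(round(score, 6), set()).add(round(pid, 6))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, n_cols + 1, n_ident + (a[i] == b[j]),
                score + matrix[a[i], b[j]], "m")
        if i < len(a):
            at_end = j == 0 or j == len(b)
            cost = 0.0 if (end_gaps_free and at_end) else (
                -gap_extend if last == "gb" else -gap_open)
            rec(i + 1, j, n_cols + 1, n_ident, score + cost, "gb")
        if j < len(b):
            at_end = i == 0 or i == len(a)
            cost = 0.0 if (end_gaps_free and at_end) else (
                -gap_extend if last == "ga" else -gap_open)
            rec(i, j + 1, n_cols + 1, n_ident, score + cost, "ga")

    rec(0, 0, 0, 0, 0.0, None)
    return results


def optimal_alignment_identities(a, b, **kwargs):
    """Set of percent identities achieved by score-optimal alignments."""
    table = enumerate_global_alignments(a, b, **kwargs)
    return max(table), table[max(table)]
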