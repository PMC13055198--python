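"""Tab-separated output of search results and pairwise matrices.

Output is deterministic byte-for-byte for fixed inputs: floats are rendered
at 4 decimals, and a '#'-prefixed comment block records the tool version
and full parameter set so a results file is self-describing.
"""

from __future__ import annotations

from os import PathLike
from typing import Optional

import numpy as np

from . import __version__
from .composition import CompositionVector
from .ranking import SearchResult, prominent_features

RESULT_COLUMNS = (
    "rank",
    "protein_id",
    "description",
    "start",
    "end",
    "window_length",
    "distance",
    "compositional_identity",
    "prominent_features",
    "matched_sequence",
)


def _param_header(result: SearchResult, top_n: Optional[int]) -> list[str]:
    p = result.params
    return [
        f"# compmatch {__version__}",
        f"# query_id={result.query_id}",
        f"# min_window={p.min_window}",
        f"# max_window={p.max_window}",
        f"# metric={p.metric}",
        f"# strict_noncanonical={str(p.strict_noncanonical).lower()}",
        f"# top_n={top_n if top_n is not None else 'all'}",
        f"# n_matches={len(result.matches)}",
        f"# n_skipped={len(result.skipped)}",
    ]


def write_results_tsv(
    result: SearchResult,
    path: str | PathLike,
    top_n: Optional[int] = None,
    include_params: bool = True,
) -> None:
    """Write a ranked search result as TSV.

    One row per match in rank order (optionally truncated to ``top_n``),
    preceded by a column header row and, unless disabled, a '#'-comment
    parameter block. Numeric scores use 4 decimal places.
    """
    matches = result.matches if top_n is None else result.matches[:top_n]
    lines: list[str] = []
    if include_params:
        lines.extend(_param_header(result, top_n))
    lines.append("\t".join(RESULT_COLUMNS))
    for rank, m in enumerate(matches, start=1):
        if result.query_composition is not None:
            subject = CompositionVector.from_sequence(m.subsequence)
            feats = ",".join(
                sorted(prominent_features(result.query_composition, subject))
            )
        else:
            feats = ""
        lines.append(
            "\t".join(
                (
                    str(rank),
                    m.protein_id,
                    _description_of(result, m.protein_id),
                    str(m.start),
                    str(m.end),
                    str(m.window_length),
                    f"{m.distance:.4f}",
                    f"{m.ci:.4f}",
                    feats,
                    m.subsequence,
                )
            )
        )
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")


def _description_of(result: SearchResult, protein_id: str) -> str:
    descriptions = getattr(result, "_descriptions", None)
    if descriptions:
        return descriptions.get(protein_id, "")
    return ""


def attach_descriptions(result: SearchResult, proteome) -> SearchResult:
    """Carry FASTA descriptions into the result for TSV rendering."""
    object.__setattr__(
        result, "_descriptions", {rec.id: rec.description for rec in proteome}
    )
    return result


def read_results_tsv(path: str | PathLike) -> tuple[dict[str, str], list[dict[str, str]]]:
    """Parse a results TSV back into (parameter dict, list of row dicts)."""
    params: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    params[key] = value
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise ValueError(f"{path}: no column header row")
    return params, rows


def write_matrix_tsv(labels, matrix: np.ndarray, path: str | PathLike) -> None:
    """Write a labeled square matrix as TSV with 4-decimal entries."""
    with open(path, "w") as out:
        out.write("\t".join(("label", *labels)) + "\n")
        for label, row in zip(labels, matrix):
            out.write("\t".join((label, *(f"{v:.4f}" for v in row))) + "\n")


def read_matrix_tsv(path: str | PathLike) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a labeled square matrix written by :func:`write_matrix_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
    return tuple(header), np.array(rows, dtype=float)
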