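"""FASTA input and output for protein records.

Parsing is strict where ambiguity would corrupt a search: duplicate
identifiers, empty sequences, internal stop symbols, and sequence data
before the first header are all errors rather than silently repaired.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited token of the header line,
    kept verbatim (UniProt-style ``sp|ACC|NAME`` headers are not split).
    ``description`` is the remainder of the header, possibly empty.
    ``sequence`` is uppercase with terminal stop symbols removed.
    """

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | PathLike) -> io.TextIOBase:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = "".join(raw.split()).upper()
    seq = seq.rstrip("*")
    if not seq:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    if "*" in seq:
        raise ValueError(f"record {record_id!r} contains an internal stop symbol")
    return seq


def read_fasta(path: str | PathLike) -> list[ProteinRecord]:
    """Read a (optionally gzipped) multi-record FASTA file.

    Record order is preserved; sequences are uppercased with line breaks
    removed and terminal ``*`` stripped. Raises ``FileNotFoundError`` for a
    missing file and ``ValueError`` for malformed content: text before the
    first ``>`` header, duplicate ids, empty sequences, internal stops.
    """
    with _open_text(path) as handle:
        text = handle.read()
    stripped = text.lstrip("\n\r \t")
    if not stripped:
        raise ValueError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise ValueError(f"{path}: sequence data before first '>' header")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for title, raw_seq in SimpleFastaParser(io.StringIO(stripped)):
        parts = title.split(None, 1)
        if not parts:
            raise ValueError(f"{path}: record with empty header")
        rec_id = parts[0]
        description = parts[1] if len(parts) > 1 else ""
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            ProteinRecord(rec_id, description, _clean_sequence(raw_seq, rec_id))
        )
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | PathLike, width: int = 60
) -> None:
    """Write records as FASTA with sequences wrapped at ``width`` columns."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
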