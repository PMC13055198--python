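"""Seeded synthetic proteomes and planted composition-matched regions.

Everything here is a pure function of its spec plus seed, so end-to-end
recovery tests have exact, reproducible ground truth: a planted region is
a random permutation of an exact residue multiset, which makes the CI-100
optimum of a matching query known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CANONICAL_AA, N_AA, CompositionVector
from .fasta import ProteinRecord

#: Background biased toward charged residues (D/E/K/R) with some small
#: hydrophobics, and zero weight on uncharged polar residues. Emulates the
#: "worst case" background for a polar-IDR search: compositionally remote
#: from Q/N-rich targets, so any planted polar region stands out only if
#: the scan actually finds it.
CHARGED_BACKGROUND = CompositionVector.from_percents(
    {"D": 20, "E": 20, "K": 18, "R": 17, "A": 10, "L": 8, "V": 7}
)

#: Q/N-rich target emulating a prion-like domain composition: dominated by
#: glutamine and asparagine with secondary uncharged polar/aromatic
#: content. Realizable as integer residue counts at window 100.
QN_RICH_TARGET = CompositionVector.from_percents(
    {"Q": 40, "N": 30, "S": 10, "G": 10, "Y": 5, "P": 5}
)

_AA_BYTES = np.frombuffer(CANONICAL_AA.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a random proteome: i.i.d. residues from a background."""

    n_proteins: int
    length_range: tuple[int, int]
    background: CompositionVector = CHARGED_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_proteins < 1 or lo < 1 or lo > hi:
            raise ValueError("invalid generator spec")
        total = float(self.background.percent.sum())
        if abs(total - 100.0) > 1e-9:
            raise ValueError("background percents must sum to 100")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one planted region (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    target_composition: CompositionVector


def _indices_to_str(idx: np.ndarray) -> str:
    return _AA_BYTES[idx].tobytes().decode("ascii")


def random_proteome(spec: GeneratorSpec) -> list[ProteinRecord]:
    """Generate ``n_proteins`` records with i.i.d. background residues."""
    rng = np.random.default_rng(spec.seed)
    weights = spec.background.percent / 100.0
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    width = len(str(spec.n_proteins))
    records = []
    for k, L in enumerate(lengths, start=1):
        idx = rng.choice(N_AA, size=int(L), p=weights)
        records.append(
            ProteinRecord(f"syn{k:0{width}d}", "synthetic background protein",
                          _indices_to_str(idx))
        )
    return records


def exact_multiset(target: CompositionVector, window: int) -> np.ndarray:
    """Residue-index multiset realizing ``target`` exactly at ``window``.

    Raises ``ValueError`` when the target percents do not translate to
    integer residue counts at the given window size — compositions are
    rejected rather than rounded so planted ground truth stays exact.
    """
    counts = target.percent * window / 100.0
    rounded = np.rint(counts)
    if np.abs(counts - rounded).max() > 1e-9:
        raise ValueError(
            f"target composition not realizable as integer counts at window {window}"
        )
    if int(rounded.sum()) != window:
        raise ValueError("target composition does not cover the full window")
    return np.repeat(np.arange(N_AA), rounded.astype(np.int64))


def random_sequence_of_composition(
    target: CompositionVector, window: int, seed: int
) -> str:
    """Random permutation of the exact residue multiset of ``target``."""
    rng = np.random.default_rng(seed)
    return _indices_to_str(rng.permutation(exact_multiset(target, window)))


def plant_region(
    proteome: list[ProteinRecord],
    target: CompositionVector,
    window: int,
    seed: int,
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """Overwrite a random slice of one protein with a shuffled target multiset.

    The chosen protein and start position are drawn uniformly among
    proteins long enough to hold the window. Returns the modified proteome
    (input is not mutated) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    multiset = exact_multiset(target, window)
    eligible = [i for i, rec in enumerate(proteome) if len(rec) >= window]
    if not eligible:
        raise ValueError(f"no protein long enough for a window of {window}")
    pick = eligible[int(rng.integers(len(eligible)))]
    rec = proteome[pick]
    start0 = int(rng.integers(len(rec) - window + 1))
    planted = _indices_to_str(rng.permutation(multiset))
    new_seq = rec.sequence[:start0] + planted + rec.sequence[start0 + window :]
    new_rec = ProteinRecord(rec.id, rec.description, new_seq)
    out = list(proteome)
    out[pick] = new_rec
    truth = PlantedTruth(
        protein_id=rec.id,
        start=start0 + 1,
        end=start0 + window,
        target_composition=target,
    )
    return out, truth
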