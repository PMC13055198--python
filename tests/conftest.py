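import numpy as np
import pytest

from compmatch import CANONICAL_AA, GeneratorSpec, ProteinRecord, random_proteome
from compmatch.composition import CompositionVector


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, length, alphabet=CANONICAL_AA):
    return "".join(rng.choice(list(alphabet), size=length))


def random_composition(rng, max_count=50):
    """Composition vector from random integer residue counts."""
    counts = rng.integers(0, max_count + 1, size=20)
    if counts.sum() == 0:
        counts[0] = 1
    total = int(counts.sum())
    return CompositionVector(percent=counts * 100.0 / total, length=total)


@pytest.fixture
def uniform_background():
    return CompositionVector.from_percents({aa: 5.0 for aa in CANONICAL_AA})


@pytest.fixture
def small_proteome(uniform_background):
    spec = GeneratorSpec(
        n_proteins=20, length_range=(60, 200), background=uniform_background, seed=11
    )
    return random_proteome(spec)


@pytest.fixture
def proteome_file(tmp_path, small_proteome):
    from compmatch import write_fasta

    path = tmp_path / "proteome.fasta"
    write_fasta(small_proteome, path)
    return path


def make_record(rec_id, seq, description=""):
    return ProteinRecord(rec_id, description, seq)
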