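import numpy as np
import pytest

from mitobias.codes import get_code
from mitobias.seq_data import Alignment, CodonAlignment


@pytest.fixture(scope="session")
def code4():
    return get_code(4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_codon_alignment(code4):
    rows = [
        "ATGAAATTTGGC",
        "ATGAAGTTCGGT",
        "ATGCGATTT---",
        "ATG???TTTGGA",
    ]
    return CodonAlignment(["t1", "t2", "t3", "t4"], rows, code4)


@pytest.fixture
def random_nt_alignment(rng):
    n_taxa, n_cols = 6, 60
    data = rng.choice(list("ACGT-?"), size=(n_taxa, n_cols), p=[0.23, 0.23, 0.23, 0.23, 0.05, 0.03])
    return Alignment([f"s{i}" for i in range(n_taxa)], data, "nt4")


def random_codon_alignment(rng, code, n_taxa=4, n_codons=30):
    """Stop-free random codon alignment."""
    sense = list(code.sense_codons)
    rows = []
    for i in range(n_taxa):
        idx = rng.integers(0, len(sense), size=n_codons)
        rows.append("".join(sense[j] for j in idx))
    return CodonAlignment([f"s{i}" for i in range(n_taxa)], rows, code)
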