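import numpy as np
import pytest

from mitocup.genetic_code import CODON_ORDER, load_code
from mitocup.codon_usage import CodonCountTable
from mitocup.seq_io import CodingSequence
from mitocup.synthetic_data import generate, make_spec


@pytest.fixture(scope="session")
def mito_code():
    return load_code("vertebrate-mito")


@pytest.fixture(scope="session")
def standard_code():
    return load_code("standard")


@pytest.fixture(scope="session")
def small_population():
    """Five kansuensis-like individuals; enough for structural checks."""
    return generate(make_spec("kansuensis-like", 11, {"n_individuals": 5}))


@pytest.fixture(scope="session")
def full_population():
    """The default study-sized population: 89 near-identical genomes."""
    return generate(make_spec("kansuensis-like", 11))


def random_count_table(rng: np.random.Generator, max_count: int = 50) -> CodonCountTable:
    counts = {c: int(rng.integers(0, max_count)) for c in CODON_ORDER}
    return CodonCountTable("random", counts)


def make_cds(seq: str, gene: str = "ND1", strand: str = "+") -> CodingSequence:
    return CodingSequence(gene=gene, seq=seq, strand=strand,
                          complete_stop=(len(seq) % 3 == 0))
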