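import logging

import numpy as np
import pytest

from ecotyping.seq_core import Alignment, SequenceRecord
from ecotyping.synthetic_data import SynthConfig, simulate_ecotype_alignment

logging.getLogger("ecotyping").setLevel(logging.ERROR)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231204)


@pytest.fixture()
def toy_alignment():
    return Alignment(
        [
            SequenceRecord("s1", "ACGTACGTAC"),
            SequenceRecord("s2", "ACGTACGTAC"),
            SequenceRecord("s3", "ACGTTCGTAC"),
            SequenceRecord("s4", "AC-TTCGTNC"),
        ]
    )


@pytest.fixture(scope="session")
def four_ecotype_data():
    """A well-separated 4-ecotype alignment with its true labels."""
    cfg = SynthConfig(n_ecotypes=4, seqs_per_ecotype=6, L=600, seed=11)
    return simulate_ecotype_alignment(cfg)
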