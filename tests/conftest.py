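import numpy as np
import pytest

from retromorf.sequence_io import AMINO_ACIDS, ProteinSequence


def random_protein(rng: np.random.Generator, length: int, rec_id: str = "q") -> ProteinSequence:
    return ProteinSequence(rec_id, "".join(rng.choice(list(AMINO_ACIDS), size=length)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20101103)


@pytest.fixture
def random_records(rng) -> list[ProteinSequence]:
    return [random_protein(rng, int(rng.integers(10, 60)), f"rec{i}") for i in range(3)]
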