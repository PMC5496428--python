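import numpy as np
import pytest

from bignorm.io import ReadRecord


def make_read(bases: str, phred: int = 40, read_id: str = "r") -> ReadRecord:
    """Uniform-quality read helper."""
    return ReadRecord(
        id=read_id, bases=bases, phreds=np.full(len(bases), phred, dtype=np.int16)
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
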