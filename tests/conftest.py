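import numpy as np
import pytest

from thermoprot.sequence_io import AMINO_ACIDS, SequenceRecord, SequenceSet


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng) -> SequenceSet:
    """20 labelled valid sequences, 10 per class."""
    records = [
        SequenceRecord(
            id=f"s{i:02d}",
            sequence=random_sequence(rng, int(rng.integers(25, 60))),
            label=i % 2,
        )
        for i in range(20)
    ]
    return SequenceSet(records, name="small")


@pytest.fixture
def tiny_fasta(tmp_path):
    p = tmp_path / "tiny.fasta"
    p.write_text(">a\nMKVLAT\n>b\nMK\nVL\n")
    return p
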