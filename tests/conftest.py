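import numpy as np
import pytest

from grvec import RESIDUE_ORDER, worked_example
from grvec.adjacency import PAIR_LABELS


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence over the canonical alphabet."""
    return "".join(rng.choice(list(RESIDUE_ORDER), size=length))


def brute_force_counts(seq: str) -> np.ndarray:
    """Independent 2-mer oracle: for each of the 400 labels, scan every
    position and count overlapping occurrences of that 2-mer."""
    out = np.zeros(400, dtype=np.int64)
    for k, label in enumerate(PAIR_LABELS):
        out[k] = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == label)
    return out


@pytest.fixture
def example_sample():
    return worked_example()


@pytest.fixture
def example_fasta(tmp_path, example_sample):
    from grvec import write_fasta

    path = tmp_path / "worked_example.fasta"
    write_fasta(example_sample, path)
    return path
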