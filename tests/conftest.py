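import numpy as np
import pytest

from genomekit.seqcore import Sequence, rand_seq


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_genome() -> dict[str, Sequence]:
    """Two random 5 kb chromosomes, fixed seed."""
    seqs = rand_seq(2, 5000, 0.45, seed=2024)
    seqs[0].name, seqs[1].name = "chr1", "chr2"
    return {s.name: s for s in seqs}


@pytest.fixture(scope="session")
def tiny_sizes(tiny_genome) -> dict[str, int]:
    return {name: len(s.seq) for name, s in tiny_genome.items()}
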