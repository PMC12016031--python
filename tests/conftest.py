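import numpy as np
import pytest

from islandmap import SequenceRecord, SimulationConfig, generate_genome


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture(scope="session")
def small_simulation():
    """One small simulated chromosome with planted truth, shared per session."""
    config = SimulationConfig(n_chroms=1, chrom_length=60_000, n_islands=4, seed=11)
    records, truth = generate_genome(config)
    return config, records, truth


@pytest.fixture
def record_factory():
    def make(seq: str, name: str = "chr1") -> SequenceRecord:
        return SequenceRecord(name, seq)

    return make
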