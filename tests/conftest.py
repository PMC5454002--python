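import numpy as np
import pytest
from hypothesis import settings

from mitecompare import SimulationConfig, generate_accession_set

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete multi-accession dataset shared across tests."""
    cfg = SimulationConfig(
        n_accessions=4,
        chromosome_lengths=(90_000, 90_000),
        n_gene_families=36,
        n_mite_families=4,
        copy_number_range=(3, 4),
        extra_copies_range=(3, 5),
        seed=11,
    )
    return generate_accession_set(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_dna(n: int, seed: int) -> str:
    r = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[r.integers(0, 4, size=n)])
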