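import numpy as np
import pytest

from lanesplit.readset import ReadSet
from lanesplit.synthdata import AbundanceProfile, gen_sc_dataset, gen_transcriptome


@pytest.fixture(scope="session")
def singleton_reads() -> ReadSet:
    """1000 distinct sequences, one instance each."""
    return ReadSet.from_sequences(f"READ{i:06d}" for i in range(1000))


@pytest.fixture(scope="session")
def toy_transcriptome():
    return gen_transcriptome(5, (300, 600), seed=101)


@pytest.fixture(scope="session")
def toy_profile(toy_transcriptome):
    return AbundanceProfile.uniform(toy_transcriptome, total=2000, duplication=1.5)


@pytest.fixture(scope="session")
def sc_truth():
    """Small clustered dataset with a driver-gene island."""
    return gen_sc_dataset(
        n_cells=300, n_genes=600, cluster_weights=(0.4, 0.3, 0.3),
        markers_per_cluster=25, island_size=30, nb_dispersion=0.1, seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
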