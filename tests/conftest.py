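import pytest

from karyoevo.history import FUSION, WGD
from karyoevo.simulate import SimulationConfig, simulate_history


@pytest.fixture(scope="session")
def lossless_sim():
    """Full vertebrate history (23 chromosomes, 3+6/9/5 fusions, two WGDs,
    5 bird-stem fusions) with no gene loss and no translocation."""
    return simulate_history(SimulationConfig(
        genes_per_chromosome=30, retention_prob=1.0, seed=7))


@pytest.fixture(scope="session")
def lossy_sim():
    """Default study conditions: G=100 genes per chromosome, p=0.9."""
    return simulate_history(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small two-WGD history without fusions, for fast structural tests."""
    return simulate_history(SimulationConfig(
        n_ancestral_chromosomes=2, genes_per_chromosome=10,
        outgroup_fusions=0, stem_events=(WGD, WGD), lineage_events={},
        retention_prob=1.0, seed=3))
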