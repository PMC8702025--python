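import pytest

from mitocomp import table1_fixture
from mitocomp.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def ped():
    """The 15,274 bp study genome annotation (coordinates only)."""
    return table1_fixture("Ped")


@pytest.fixture(scope="session")
def ppr():
    """The 16,031 bp study genome annotation (coordinates only)."""
    return table1_fixture("Ppr")


@pytest.fixture(scope="session")
def sim_genome():
    """One default simulated genome, shared across tests."""
    return simulate_annotation(SimulationConfig(seed=1))
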