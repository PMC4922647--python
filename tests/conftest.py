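import pytest

from b73prov import synth
from b73prov.genotyping import build_matrix, paralog_filter, segregating_sites


@pytest.fixture(scope="session")
def default_sim() -> synth.SimResult:
    """One default-condition simulation shared across the suite."""
    return synth.simulate(synth.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    """The default simulation's filtered, segregating genotype matrix."""
    return segregating_sites(
        paralog_filter(build_matrix(default_sim.depths))
    )
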