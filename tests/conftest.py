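import numpy as np
import pytest

from netdriver import (
    GeneNetwork,
    NullEnsemble,
    gen_network,
    generate_scenario,
    run_pipeline,
)


@pytest.fixture
def star():
    """Hub H connected to A, B, C."""
    return GeneNetwork.from_edges([("H", "A"), ("H", "B"), ("H", "C")])


@pytest.fixture
def triangle():
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def path3():
    """Path A - H - B."""
    return GeneNetwork.from_edges([("A", "H"), ("H", "B")])


@pytest.fixture(scope="session")
def er_network():
    """Erdős–Rényi background network, 500 nodes, mean degree 8."""
    return gen_network(500, 8.0, "ER", seed=5)


@pytest.fixture(scope="session")
def er_ensemble(er_network):
    return NullEnsemble.for_network(er_network, seed=13)


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic study: BA(1000) network, 5 planted modules of 15
    (intra-module edge probability 0.6), 50 samples with 5 drivers + 20
    passengers each, CNA segments with 5 carriers per planted driver."""
    return generate_scenario(seed=1)


@pytest.fixture(scope="session")
def default_pipeline_result(default_scenario):
    sc = default_scenario
    return run_pipeline(
        sc.truth.network,
        sc.maf_records,
        sc.truth.modules,
        cna_profile=sc.cna_profile,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
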