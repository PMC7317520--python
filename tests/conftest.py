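import numpy as np
import pytest

import dmfa
from dmfa.design import InflectionGrid


@pytest.fixture(scope="session")
def demo_net():
    return dmfa.demo_network()


@pytest.fixture(scope="session")
def batch_net():
    return dmfa.demo_network(reversible_lactate=False)


@pytest.fixture(scope="session")
def simple_case():
    """Simulated 4-EM batch run with one noisy sample and a fit grid."""
    scen = dmfa.simple_scenario(seed=2)
    result = dmfa.simulate(scen)
    data = dmfa.sample_measurements(result, rng=np.random.default_rng(5))
    grid = InflectionGrid.from_span(0.0, 60.0, 5)
    return {"scenario": scen, "result": result, "data": data, "grid": grid}


@pytest.fixture(scope="session")
def fedbatch_case():
    """Simulated fed-batch run on the reversible-lactate network."""
    scen = dmfa.default_scenario(seed=1)
    result = dmfa.simulate(scen)
    data = dmfa.sample_measurements(result, rng=np.random.default_rng(3))
    grid = InflectionGrid.from_span(0.0, 120.0, 5)
    return {"scenario": scen, "result": result, "data": data, "grid": grid}


@pytest.fixture(scope="session")
def pwl():
    """Linear-model fixture: truth inside the estimator's model class."""
    return dmfa.piecewise_linear_fixture()
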