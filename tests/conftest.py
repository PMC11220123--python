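import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phcdea import pipeline, spatial, synthetic


@pytest.fixture(scope="session")
def default_panel():
    """Default-regime synthetic panel with truth (31 provinces x 9 years)."""
    cfg = synthetic.SimulationConfig(seed=123)
    return synthetic.generate_panel(cfg)


@pytest.fixture(scope="session")
def province_weights():
    labels, _, edges, _ = synthetic.province_fixture()
    return spatial.weights_from_edges(labels, edges)


@pytest.fixture(scope="session")
def small_run(province_weights):
    """One full three-stage run on a shorter panel, shared across tests."""
    cfg = synthetic.SimulationConfig(seed=9, n_years=4)
    panel, truth = synthetic.generate_panel(cfg)
    result = pipeline.run_three_stage(
        panel, province_weights, {"seed": 9, "n_perm": 199})
    return panel, truth, result


@pytest.fixture
def toy_1x1():
    """A(2,2), B(4,2), C(3,3): B is half as input-efficient as A."""
    X = np.array([[2.0], [4.0], [3.0]])
    Y = np.array([[2.0], [2.0], [3.0]])
    return X, Y
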