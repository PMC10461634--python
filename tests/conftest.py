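import numpy as np
import pytest

import isletsim as s


@pytest.fixture(scope="session")
def params() -> s.ModelParameters:
    return s.ModelParameters()


@pytest.fixture(scope="session")
def basal() -> s.BasalState:
    return s.BasalState()


@pytest.fixture(scope="session")
def perifusion_15() -> s.Protocol:
    """Standard 15-islet, 1 mL, 1 mL/min perifusion protocol."""
    return s.Protocol(mode="perifusion", volume=1.0, flow=1.0, n_islets=15, duration=60.0)


@pytest.fixture(scope="session")
def pancreas_normal(params):
    return s.whole_pancreas(params)


@pytest.fixture(scope="session")
def pancreas_t1d(params):
    return s.whole_pancreas(params, diabetic=True)


@pytest.fixture(scope="session")
def batch_sweep_10(params):
    """Total 1-h secretion, 10 islets in a 1 mL batch chamber, steps from 1 mM."""
    return s.islet_number_sweep(
        params, glucose_levels=(1, 7, 30), islet_counts=(10,), mode="batch"
    )


@pytest.fixture(scope="session")
def perifusion_sweep_15(params):
    return s.islet_number_sweep(
        params, glucose_levels=(1, 7, 30), islet_counts=(15,), mode="perifusion"
    )
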