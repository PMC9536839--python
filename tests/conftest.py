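import numpy as np
import pytest

from methyldyn.spin import Experiment, ExchangeModel, ExperimentGeometry
from methyldyn.synthetic import default_scenario, generate_cest_tables, generate_cpmg_tables

NU_GRID = tuple(np.arange(25.0, 1001.0, 25.0))


@pytest.fixture(scope="session")
def sq_geom():
    return ExperimentGeometry(Experiment.SQ_CPMG, 850.0, 0.04, NU_GRID)


@pytest.fixture(scope="session")
def mq_geom():
    return ExperimentGeometry(Experiment.MQ_CPMG, 850.0, 0.04, NU_GRID)


@pytest.fixture(scope="session")
def cest_geom():
    return ExperimentGeometry(
        Experiment.CEST, 600.0, 0.4,
        offset_list=tuple(np.arange(-300.0, 410.0, 10.0)), spinlock_power=25.0,
    )


@pytest.fixture(scope="session")
def slow_model():
    """The concerted slow process: kex = 240 s^-1, p_B = 1.3%."""
    return ExchangeModel(k_ab=3.12, k_ba=236.88, dw_C_ab=1.0, r2_base=10.0,
                         r1_base=2.0)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=42)


@pytest.fixture(scope="session")
def scenario_tables(scenario):
    return {
        "cpmg": generate_cpmg_tables(scenario),
        "cest": generate_cest_tables(scenario),
    }
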