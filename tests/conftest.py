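import logging

import pytest
from hypothesis import HealthCheck, settings

from pangraphsv import synthetic_data as sd

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

logging.getLogger("pangraphsv").setLevel(logging.ERROR)

DESK_SEED = 11


@pytest.fixture(scope="session")
def desk_cfg() -> sd.SimConfig:
    return sd.desk_preset(seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_truth(desk_cfg):
    return sd.simulate_population(desk_cfg)


@pytest.fixture(scope="session")
def desk_graph_paths(desk_truth):
    return sd.emit_graph_and_paths(desk_truth)


@pytest.fixture(scope="session")
def desk_records(desk_graph_paths):
    from pangraphsv import call_svs

    graph, paths = desk_graph_paths
    return call_svs(graph, paths)
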