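import numpy as np
import pytest

from reflexdna import CircuitParams, build_two_input_circuit


@pytest.fixture(scope="session")
def default_params():
    return CircuitParams()


@pytest.fixture(scope="session")
def two_input_network(default_params):
    return build_two_input_circuit(default_params)


@pytest.fixture(scope="session")
def bfb_run(default_params):
    """Prelearning probe: pattern B-F-B at defaults (shared across tests)."""
    from reflexdna import run_pattern

    return run_pattern(default_params, "B-F-B")


@pytest.fixture(scope="session")
def bfbb_run(default_params):
    """Learning probe: pattern B-FB-B at defaults (shared across tests)."""
    from reflexdna import run_pattern

    return run_pattern(default_params, "B-FB-B")
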