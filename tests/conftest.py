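import numpy as np
import pytest

from redeval import (
    build_simple_example,
    eligible_complexes,
    resolve_horizon,
    steady_state,
)


@pytest.fixture(scope="session")
def simple():
    """The four-compound example network with reference parameters."""
    return build_simple_example()


@pytest.fixture(scope="session")
def simple_xss(simple):
    model, params = simple
    return steady_state(model, params)


@pytest.fixture(scope="session")
def simple_horizon(simple, simple_xss):
    model, params = simple
    return resolve_horizon(model, params, xss=simple_xss)


@pytest.fixture(scope="session")
def simple_eligible(simple):
    return tuple(eligible_complexes(simple[0]))
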