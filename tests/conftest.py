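import numpy as np
import pytest

from cyclekin import models, state_probability_expressions


@pytest.fixture(scope="session")
def four_state():
    diagram, parameter_map = models.build_four_state()
    return diagram, parameter_map


@pytest.fixture(scope="session")
def four_state_expressions(four_state):
    return state_probability_expressions(four_state[0])


@pytest.fixture(scope="session")
def six_state_leak():
    return models.build_six_state(with_leak=True)


@pytest.fixture(scope="session")
def six_state_leak_expressions(six_state_leak):
    return state_probability_expressions(six_state_leak[0])


@pytest.fixture(scope="session")
def emre():
    return models.build_emre()


@pytest.fixture(scope="session")
def emre_expressions(emre):
    return state_probability_expressions(emre[0])


@pytest.fixture
def triangle():
    matrix = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    from cyclekin import load_diagram

    return load_diagram(matrix)
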