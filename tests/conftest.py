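import pytest

from nmrcase.case_generator import GeneratorConfig, generate
from nmrcase.fixtures import caffeine
from nmrcase.theo_calc import backcalc

CAFFEINE_RUN_CONFIG = GeneratorConfig(
    fourj_flag=0,
    forbidden_bonds=frozenset({frozenset({"N", "N"}), frozenset({"N", "O"})}),
)


@pytest.fixture(scope="session")
def caffeine_graph():
    return caffeine()


@pytest.fixture(scope="session")
def caffeine_cs(caffeine_graph):
    return backcalc(caffeine_graph)


@pytest.fixture(scope="session")
def caffeine_solutions(caffeine_graph, caffeine_cs):
    """The caffeine ambiguity run (N-N/N-O forbidden, no 4J), shared across
    tests because it is the heaviest generation in the suite."""
    return generate(caffeine_graph.atoms, caffeine_cs, CAFFEINE_RUN_CONFIG)
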