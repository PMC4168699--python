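import pytest

import cerebroflow as cf


@pytest.fixture(scope="session")
def bc():
    return cf.BoundaryConditions()


@pytest.fixture(scope="session")
def canonical():
    """Canonical network without anastomoses."""
    return cf.build_network()


@pytest.fixture(scope="session")
def baseline_solution(canonical, bc):
    return cf.solve_flow(canonical, bc)


@pytest.fixture(scope="session")
def suites():
    """Experiment suites for the three studied LA conditions (cached)."""
    return {
        cond: cf.run_experiment_suite(la_config=la)
        for cond, la in cf.CONDITIONS.items()
    }
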