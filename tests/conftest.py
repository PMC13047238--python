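import numpy as np
import pytest

import idmauc as m


@pytest.fixture(scope="session")
def truth_params():
    return m.SIMULATION_TRUTH


@pytest.fixture(scope="session")
def scenario_a_data():
    """One scenario-A dataset (N=1000, Unif(5,10)y censoring, 3-month visits)."""
    return m.simulate_scenario(m.scenario("A", seed=20260920))


@pytest.fixture(scope="session")
def small_panel():
    """Tiny hand-checkable panel: one diagnosed death, one direct death,
    one censored disease-free subject."""
    return m.PanelDataset(
        [
            m.SubjectRecord("s1", [0.0, 3.0, 6.0, 9.0], [0, 0, 1, 1], 14.0, 1),
            m.SubjectRecord("s2", [0.0, 3.0, 6.0], [0, 0, 0], 7.2, 0),
            m.SubjectRecord("s3", [0.0], [0], 1.5, 1),
        ]
    )
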