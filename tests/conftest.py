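import numpy as np
import pytest

import respsig as rs
from respsig.simulate import INDICATORS, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic cohort (3 x 9 swimmers), fixed seed."""
    return generate_cohort(SimulationConfig(seed=20260930))


@pytest.fixture(scope="session")
def default_delta(default_panel):
    u = rs.fit_baseline_pca(default_panel, "upper", INDICATORS["upper"])
    l = rs.fit_baseline_pca(default_panel, "lower", INDICATORS["lower"])
    return rs.compute_deltas(u, l, default_panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
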