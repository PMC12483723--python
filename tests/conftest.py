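import logging

import numpy as np
import pytest

from ordalt.estimation import compute_sample_stats
from ordalt.models import build_spec, sample_admissible_theta
from ordalt.simulate import SimScenario, simulate

logging.getLogger("ordalt").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def alt_probe_panel():
    """One misspecified-for-everything probe panel (saturated truth, T=5, C=4)."""
    gen = build_spec("saturated", "standard", 5, 4)
    theta = sample_admissible_theta(gen, np.random.default_rng(31))
    return simulate(SimScenario(gen, theta, n=2000), seed=31)


@pytest.fixture(scope="session")
def alt_probe_stats(alt_probe_panel):
    return compute_sample_stats(alt_probe_panel)


@pytest.fixture(scope="session")
def binary_probe_stats():
    gen = build_spec("saturated", "standard", 5, 2)
    theta = sample_admissible_theta(gen, np.random.default_rng(41))
    panel = simulate(SimScenario(gen, theta, n=2000), seed=41)
    return compute_sample_stats(panel)
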