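"""Shared fixtures: small seeded problems reused across the suite."""

import logging

import numpy as np
import pytest

from neuroea.efeatures import FeatureSet
from neuroea.fixtures import TOY_FEATURES, make_ground_truth, make_toy_problem
from neuroea.stimuli import StimulusSuite, make_long_square

logging.getLogger("neuroea").setLevel(logging.ERROR)


def short_suite():
    """Three brief long squares (sub-, near-, supra-threshold) on a short
    time base — cheap enough for scheduler and scoring tests."""
    return StimulusSuite(tuple(
        make_long_square(amp, delay=50.0, duration=200.0, t_stop=300.0,
                         stimulus_id=f"step_{i}")
        for i, amp in enumerate((0.05, 0.2, 0.4))
    ))


@pytest.fixture(scope="session")
def small_gtp():
    """2-free-parameter ground truth on the short suite with 8 features."""
    return make_ground_truth(7, n_free_params=2, suite=short_suite(),
                             feature_set=FeatureSet(TOY_FEATURES))


@pytest.fixture(scope="session")
def small_problem(small_gtp):
    return small_gtp.problem()


@pytest.fixture(scope="session")
def toy2():
    """The shipped 2-parameter recovery toy (8 long squares x 8 features)."""
    return make_toy_problem(n_free_params=2)


@pytest.fixture(scope="session")
def gtp_full():
    """Full 13-parameter problem: 18 stimuli x 20 features, noiseless."""
    return make_ground_truth(1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
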