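"""Shared fixtures: all test data is generated programmatically."""

import logging

import numpy as np
import pytest

import dcelogit as d

logging.getLogger("dcelogit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schema():
    return d.default_schema()


@pytest.fixture(scope="session")
def small_design(schema):
    return d.generate_design(schema, n_tasks=6, n_alts=2, seed=11)


@pytest.fixture(scope="session")
def small_respondents():
    return d.generate_respondents(25, seed=22)


@pytest.fixture(scope="session")
def simple_prefs(schema):
    """Moderate MNL/RPL truth with no interactions."""
    return d.TruePreferences(
        beta=np.array([-0.2, 0.1, 1.3, 0.5, 0.5, -0.2, 0.3, -0.003]),
        chol=np.diag([0.2, 0.1, 1.1, 0.5, 0.3, 0.4, 0.3, 0.004]),
        asc=-2.4,
    )


@pytest.fixture(scope="session")
def mnl_prefs(schema):
    return d.TruePreferences(
        beta=np.array([-0.2, 0.1, 1.3, 0.5, 0.5, -0.2, 0.3, -0.003]),
        asc=-2.4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design, small_respondents, simple_prefs):
    """25 respondents x 6 tasks simulated from an RPL process."""
    return d.simulate_choices(small_design, small_respondents, simple_prefs, family="rpl", seed=33)


@pytest.fixture(scope="session")
def tiny_dataset(schema, simple_prefs):
    """3 respondents x 2 tasks, small enough for brute-force oracles."""
    design = d.generate_design(schema, n_tasks=2, n_alts=2, seed=44)
    resp = d.generate_respondents(3, seed=55)
    return d.simulate_choices(design, resp, simple_prefs, family="rpl", seed=66)
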