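"""Shared fixtures: small simulated subjects and processed cohorts.

Heavy fixtures are session-scoped so the expensive chains (lag searches,
network training) run once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemomap.grrs import run_grrs
from hemomap.hc_reference import run_hc_reference
from hemomap.synth import LesionSpec, SimulationConfig, simulate_subject


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small fast grid used by most unit tests."""
    return SimulationConfig(grid_shape=(32, 40, 12), n_timepoints=150, seed=5)


@pytest.fixture(scope="session")
def noiseless_subject(small_config):
    """One noiseless subject on the small grid."""
    return simulate_subject(small_config.noiseless())


@pytest.fixture(scope="session")
def noisy_subject(small_config):
    return simulate_subject(small_config)


@pytest.fixture(scope="session")
def grrs_noiseless(noiseless_subject):
    """Full GRRS outputs (CVR + BAT + residual) on the noiseless subject."""
    t = noiseless_subject.truth
    return run_grrs(noiseless_subject.rest_bold, t.cerebellum_mask,
                    t.brain_mask, noiseless_subject.rest_motion)


@pytest.fixture(scope="session")
def hc_noiseless(noiseless_subject):
    """Full hypercapnic outputs on the noiseless subject."""
    t = noiseless_subject.truth
    return run_hc_reference(noiseless_subject.hc_bold,
                            noiseless_subject.hc_etco2, t.brain_mask,
                            t.cerebellum_mask)


@pytest.fixture(scope="session")
def comparison_study():
    """The scaled method-comparison study (simulate, process, train full +
    ablated networks, evaluate).  This is the slowest fixture in the suite;
    every cohort-level claim shares it."""
    from hemomap.studies import StudyConfig, run_method_comparison_study

    return run_method_comparison_study(StudyConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
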