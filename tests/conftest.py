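"""Shared fixtures: small synthetic recordings and cohorts.

Expensive artefacts (simulated recordings, cohort feature tables) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from neomaturity.pipeline import RunConfig
from neomaturity.synthetic_data import SimulationConfig, simulate_cohort, simulate_eeg


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """Short recordings (10 min QS inside 20 min) to keep tests fast."""
    return SimulationConfig(
        n_infants=4, seed=11, duration_s=1200, qs_onset_s=120, qs_duration_s=600
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return simulate_cohort(small_sim_config)


@pytest.fixture(scope="session")
def one_recording(small_sim_config, small_cohort):
    """One simulated T1 recording with annotations and ground truth."""
    _, _, truth = small_cohort
    info = {**truth["infants"]["sim001"], "infant_id": "sim001"}
    return simulate_eeg(info, "T1", small_sim_config)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
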