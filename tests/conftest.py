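"""Shared fixtures: simulated standard trials and their analyses."""

import numpy as np
import pytest

from glidekin import MorphRecord, PipelineConfig, analyze_trial
from glidekin.simulate import default_sim_config, simulate_glide


@pytest.fixture(scope="session")
def young_morph() -> MorphRecord:
    """Morphometrics of a newly hatched nymph (printed 0-DAH endpoints)."""
    return MorphRecord(mass_mg=22.7, body_length_mm=20.0,
                       planform_area_mm2=66.1, age_group="0-DAH")


@pytest.fixture(scope="session")
def std_pair():
    """Noise-free standard transition trial and its ground truth."""
    return simulate_glide(default_sim_config(seed=1))


@pytest.fixture(scope="session")
def std_trial(std_pair):
    return std_pair[0]


@pytest.fixture(scope="session")
def std_truth(std_pair):
    return std_pair[1]


@pytest.fixture(scope="session")
def std_analysis(std_pair):
    """Full pipeline run on the noise-free standard trial (interpolating fit)."""
    trial, _ = std_pair
    return analyze_trial(trial, PipelineConfig(smoothing_tolerance=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
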