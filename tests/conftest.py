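import numpy as np
import pytest

from thermocontrast.protocol import ProtocolConstants
from thermocontrast.synthetic_data import (
    PopulationConfig,
    SubjectParams,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def constants() -> ProtocolConstants:
    return ProtocolConstants()


@pytest.fixture
def quiet_subject() -> SubjectParams:
    """Deterministic subject: no rating noise, calibrated fixed point at 47 °C."""
    return SubjectParams(t50=47.0, slope_k=1.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """Six-subject simulated experiment shared across read-only tests."""
    cfg = PopulationConfig(n_subjects=6, seed=42)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def exp1_dataset():
    """Experiment-1-shaped cohort: 21 women."""
    cfg = PopulationConfig(n_subjects=21, proportion_female=1.0, seed=7)
    return simulate_experiment(cfg)
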