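import numpy as np
import pytest

from exostrength import SimulationConfig, generate_cohort, generate_session, get_protocol
from exostrength.synthetic_data import _spawn, plan_repetitions


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(master_seed=7)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        master_seed=7, noise_sd=0.0, mains_amp=0.0, torque_noise_sd=0.0,
        pace_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def squat_const_session(sim_config, cohort):
    """One default-noise metronome-paced squat session."""
    return generate_session(cohort[0], get_protocol("squat", "const"), config=sim_config)


@pytest.fixture(scope="session")
def noiseless_squat_session(noiseless_config, cohort):
    return generate_session(
        cohort[0], get_protocol("squat", "const"), config=noiseless_config
    )


@pytest.fixture(scope="session")
def fast_metric_cohort(sim_config, cohort):
    """Planted repetition series for a 30-participant squat-max cohort.

    Uses the repetition-planning fast path (no waveform synthesis), which
    is exact ground truth for the pace-derived metrics.
    """
    proto = get_protocol("squat", "max")
    out = {}
    for p in cohort:
        rng = _spawn(sim_config.master_seed, p.seed, 2)
        out[p.id] = plan_repetitions(p, proto, None, sim_config, rng)
    return out
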