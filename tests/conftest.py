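"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

import hemodyn as hd


@pytest.fixture(scope="session")
def var_spec():
    """The package's default slow-fluctuation VAR(2)."""
    return hd.default_var_spec()


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, fluctuation-free 60 s recording at constant heart rate."""
    return hd.SimulationConfig(
        seed=11, duration=60.0, noise_sd_pressure=0.0, noise_sd_flow=0.0, var_spec=None
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return hd.simulate_waveforms(clean_config)


@pytest.fixture(scope="session")
def noisy_recording():
    cfg = hd.SimulationConfig(seed=12, duration=60.0)
    return hd.simulate_waveforms(cfg)


@pytest.fixture(scope="session")
def bolus_table():
    """Beat table with a single clean vasoconstrictor bolus at t = 150 s."""
    event = hd.BolusEventSpec(
        time=150.0, peak_mult=1.8, time_to_peak=10.0, k=0.08, plateau_frac=0.15
    )
    cfg = hd.SimulationConfig(seed=21, duration=400.0, var_spec=None, boluses=(event,))
    return hd.simulate_beats(cfg), event, cfg


@pytest.fixture(scope="session")
def lps_beat_table():
    """Full three-phase endotoxin-like recording at beat resolution."""
    schedule = hd.lps_schedule()
    cfg = hd.SimulationConfig(seed=31, duration=schedule.span[1], schedule=schedule)
    return hd.simulate_beats(cfg), schedule
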