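"""Shared fixtures: synthetic trials rendered once per session."""

import warnings

import numpy as np
import pytest

from heelstrike import PipelineConfig, process_records
from heelstrike.synthetic import SimConfig, render_trial


def make_clean_config(**overrides) -> SimConfig:
    """Noiseless default trial configuration."""
    base = dict(noise_marker_sd=0.0, noise_channel_sd=0.0, sync_jitter=0.0)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_trial():
    """Noiseless default trial: (channels, markers, truth, config)."""
    cfg = make_clean_config()
    rec, markers, truth = render_trial(cfg)
    return rec, markers, truth, cfg


@pytest.fixture(scope="session")
def clean_result(clean_trial):
    """Pipeline output + intermediates for the noiseless default trial."""
    rec, markers, truth, cfg = clean_trial
    result, inter = process_records(
        rec, markers, PipelineConfig(body_mass=76.7), return_intermediates=True
    )
    return result, inter


@pytest.fixture(scope="session")
def noisy_trial():
    """Trial with study-level noise: 0.1 mm markers, 0.25 N channels, 0.8 ms jitter."""
    cfg = SimConfig(noise_marker_sd=1e-4, noise_channel_sd=0.25,
                    sync_jitter=8e-4, seed=42)
    rec, markers, truth = render_trial(cfg)
    return rec, markers, truth, cfg


@pytest.fixture(scope="session")
def undamped_trial():
    """Conservative contact (c = 0): peak force at maximal compression."""
    cfg = make_clean_config(c=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # t_p ~ t_e triggers the order warning
        rec, markers, truth = render_trial(cfg)
    return rec, markers, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
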