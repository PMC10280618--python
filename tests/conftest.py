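"""Shared fixtures: small, fully synthetic inputs generated at test time."""

import numpy as np
import pytest

from glucoppg import SynthConfig, generate_measurement
from glucoppg.synth import clean_config


@pytest.fixture(scope="session")
def fast_cfg() -> SynthConfig:
    """A scaled-down campaign: short records and a modest fast rate keep
    the SSA and feature stages quick while preserving >= 30 s tachograms."""
    return SynthConfig(
        n_subjects=2,
        measurements_per_subject=10,
        duration_s=40.0,
        fs_slow=50.0,
        fs_fast=250.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def clean_cfg(fast_cfg) -> SynthConfig:
    return clean_config(fast_cfg)


@pytest.fixture(scope="session")
def measurement(fast_cfg):
    """One raw (noisy) synthetic measurement."""
    return generate_measurement(fast_cfg, 0, 0, acq_time_h=9.0, glucose=6.2)


@pytest.fixture(scope="session")
def clean_measurement(clean_cfg):
    """One noise-free synthetic measurement (planted-signal checks)."""
    return generate_measurement(clean_cfg, 0, 0, acq_time_h=9.0, glucose=6.2)


def make_feature_table(n_rows: int, n_features: int, seed: int, noise_sd: float = 0.3):
    """Synthetic regression table with a cubic feature-glucose coupling.

    Each feature column is a distinct cubic of the glucose value plus
    white noise; used by smoothing/fusion/model tests that do not need
    the PPG waveform stage.
    """
    rng = np.random.default_rng(seed)
    glucose = rng.uniform(4.0, 11.0, size=n_rows)
    coefs = rng.normal(size=(n_features, 4)) * np.array([1.0, 0.5, 0.1, 0.02])
    g = (glucose - 7.0) / 3.0  # conditioned abscissa for the planted cubics
    X = np.stack([c[0] + c[1] * g + c[2] * g**2 + c[3] * g**3 for c in coefs], axis=1)
    X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X, glucose


@pytest.fixture()
def feature_table():
    return make_feature_table(48, 30, seed=7)
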