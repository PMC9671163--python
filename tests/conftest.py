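"""Shared fixtures: small simulated studies and a temp-file WAV writer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.io import wavfile

from duetflow import SimConfig, simulate_study
from duetflow.pipeline import AnalysisOptions, analyse_synthetic_study


@pytest.fixture
def write_wav(tmp_path):
    """Write int16 PCM samples (scaled from [-1, 1]) to a temp WAV file."""

    def _write(samples: np.ndarray, rate: int = 44100, name: str = "test.wav", raw=None):
        path = tmp_path / name
        if raw is not None:
            wavfile.write(path, rate, raw)
        else:
            pcm = np.round(np.asarray(samples) * 2**15).astype(np.int16)
            wavfile.write(path, rate, pcm)
        return path

    return _write


@pytest.fixture(scope="session")
def small_study():
    """A 3-participant x 4-trial x 60-s simulated study (fast)."""
    return simulate_study(SimConfig(participants=3, trials=4, duration=60.0, seed=11))


@pytest.fixture(scope="session")
def full_study_bundle():
    """One analysed 8 x 8 x 90-s study at default analysis options."""
    study = simulate_study(SimConfig(seed=5))
    return analyse_synthetic_study(study, AnalysisOptions())


def make_mixed_table(
    beta: float, sigma_participant: float, sigma_resid: float,
    participants: int = 8, trials: int = 8, seed: int = 0, intercept: float = 0.1,
) -> pd.DataFrame:
    """Simulate one balanced random-intercept dataset as a long table."""
    rng = np.random.default_rng(seed)
    part = np.repeat(np.arange(participants), trials)
    trial = np.tile(np.arange(1, trials + 1), participants).astype(float)
    y = (
        intercept
        + beta * trial
        + rng.normal(0.0, sigma_participant, participants)[part]
        + rng.normal(0.0, sigma_resid, participants * trials)
    )
    return pd.DataFrame({"participant": part, "trial": trial, "value": y})
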