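"""Shared fixtures: simulated subjects are expensive, so build them once."""

import logging

import numpy as np
import pytest

import wfmr
from wfmr import simulate

logging.getLogger("wfmr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def nonclinical_subject() -> wfmr.SubjectRecord:
    return wfmr.simulate_subject("nonclinical", seed=7)


@pytest.fixture(scope="session")
def clinical_subject() -> wfmr.SubjectRecord:
    return wfmr.simulate_subject("clinical", seed=11)


@pytest.fixture(scope="session")
def clean_ecg_with_truth():
    """Noise-free ECG + ground truth (mixed intrinsic beats, 300 s)."""
    cfg = wfmr.SubjectSimConfig(noise_sd=0.0, seed=21)
    rng = np.random.default_rng(21)
    r, types = simulate.simulate_beat_times(cfg, rng)
    ecg, truth = simulate.simulate_ecg(cfg, rng=rng, r_times=r, beat_types=types)
    return ecg, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
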