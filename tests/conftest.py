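"""Shared fixtures: synthetic recordings and feature matrices.

Expensive artifacts (the default-condition LOSO report, the clean waveform
corpus) are session-scoped so several test modules can share them.
"""

import numpy as np
import pytest

from volstate import (GeneratorConfig, baseline_normalize,
                      generate_feature_matrix, generate_subject,
                      loso_evaluate)


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, jitter-free generator settings for oracle comparisons."""
    return GeneratorConfig(
        n_subjects=1, beats_per_state=(30, 40, 60),
        noise_sd={"ecg": 0.0, "scg_ap": 0.0, "acc": 0.0, "ppg": 0.0},
        wander_amp=0.0, latency_jitter_s=0.0, amp_jitter_frac=0.0,
        rr_jitter_s=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_subject(clean_config, 0, seed=11)


@pytest.fixture(scope="session")
def small_recording():
    """A short recording with default (noisy) generator settings."""
    cfg = GeneratorConfig(n_subjects=1, beats_per_state=(40, 50, 70))
    return generate_subject(cfg, 0, seed=23)


@pytest.fixture(scope="session")
def default_matrix():
    """Feature matrix under the default study conditions (4 subjects,
    ~3000 beats each, ~10:1 hypovolemia imbalance)."""
    return generate_feature_matrix(GeneratorConfig(), seed=101)


@pytest.fixture(scope="session")
def default_loso_report(default_matrix):
    return loso_evaluate(baseline_normalize(default_matrix))


@pytest.fixture(scope="session")
def tiny_matrix():
    """A small 4-subject matrix for fast structural tests."""
    cfg = GeneratorConfig(n_subjects=4, beats_per_state=(40, 60, 100))
    return generate_feature_matrix(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
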