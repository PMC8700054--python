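"""Shared fixtures: small synthetic corpora and feature datasets.

Everything is generated at test time from the package's own synthetic-call
generator; reduced rates/durations keep the unit suite fast while the
acceptance tests use the full study geometry.
"""

import numpy as np
import pytest

from croak.audio_io import standardize
from croak.dataset import build_dataset
from croak.mfcc_features import MFCCConfig
from croak.synthetic_calls import generate_corpus

SMALL_RATE = 8000.0
SMALL_DURATION = 2.0


@pytest.fixture(scope="session")
def small_corpus():
    """5 species x 1 clip, 2 s at 8 kHz, standardized."""
    clips = generate_corpus(5, 1, rate=SMALL_RATE, duration=SMALL_DURATION, seed=11)
    return [standardize(c, SMALL_RATE, SMALL_DURATION) for c in clips]


@pytest.fixture(scope="session")
def grouped_corpus():
    """5 species x 3 clips for group-aware splitting tests."""
    clips = generate_corpus(5, 3, rate=SMALL_RATE, duration=SMALL_DURATION, seed=13)
    return [standardize(c, SMALL_RATE, SMALL_DURATION) for c in clips]


@pytest.fixture(scope="session")
def small_lpc_dataset(small_corpus):
    """5 species x 8 LPC orders, 256-point envelopes."""
    return build_dataset(
        small_corpus, "LPC", grid=[22, 30, 40, 50, 60, 70, 80, 90], n_points=256
    )


@pytest.fixture(scope="session")
def small_mfcc_dataset(small_corpus):
    cfg = MFCCConfig(frame_len=512, hop_len=256, target_len=256)
    return build_dataset(
        small_corpus,
        "MFCC",
        grid=[0.22, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0],
        n_points=256,
        mfcc_config=cfg,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
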