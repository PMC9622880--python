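"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

from memtopo import (
    GeneratorConfig,
    default_effects,
    generate_behavior,
    generate_brain,
    make_atlas,
)


@pytest.fixture(scope="session")
def small_sessions():
    """Six sessions of 100 videos at default study conditions."""
    cfg = GeneratorConfig(n_samples=6, n_videos_per_sample=100, seed=11)
    return generate_behavior(cfg)


@pytest.fixture(scope="session")
def atlas16():
    return make_atlas((16, 16, 16))


@pytest.fixture(scope="session")
def planted_stacks(small_sessions, atlas16):
    return generate_brain(small_sessions, atlas16, default_effects(), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
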