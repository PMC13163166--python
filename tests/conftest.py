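"""Shared fixtures: random hypnogram factories and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from sleepfrag.hypnogram import Hypnogram
from sleepfrag.simulate import GeneratorConfig, generate_cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_hypnogram(rng):
    """Factory for random five-stage hypnograms (optionally with UNSCORED)."""

    def make(
        n: int = 60,
        epoch_seconds: float = 30.0,
        p_unscored: float = 0.0,
        subject_id: str = "RND",
        generator: np.random.Generator | None = None,
    ) -> Hypnogram:
        g = generator or rng
        codes = g.integers(0, 5, size=n).astype(np.int8)
        if p_unscored > 0:
            mask = g.random(n) < p_unscored
            codes[mask] = 5
        return Hypnogram(subject_id, codes, epoch_seconds, 0, n)

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A small full-default-structure cohort reused across statistics tests."""
    cfg = GeneratorConfig(
        n_patients=30, n_siblings=30, night_length_miniepochs=2880, seed=42
    )
    return generate_cohort(cfg)
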