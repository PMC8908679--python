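"""Shared fixtures: a small fast simulation preset and pre-built runs."""

from __future__ import annotations

import numpy as np
import pytest

from svld.datamodel import VType
from svld.simulate import (
    PopulationConfig,
    SimConfig,
    error_free,
    simulate_all,
)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A reduced preset (1 chromosome, 45 samples) for fast tests."""
    defaults = dict(
        seed=seed,
        populations={
            "WL": PopulationConfig(15, 3, 40_000.0),
            "BL": PopulationConfig(15, 4, 20_000.0),
            "BR": PopulationConfig(15, 6, 10_000.0),
        },
        chromosome_lengths={"1": 1_500_000},
        sv_counts={VType.DEL: 24, VType.DUP: 12, VType.INV: 12, VType.BND: 8},
        n_artifact_regions=2,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free small simulation (perfect callers, noise-free depth)."""
    return simulate_all(error_free(small_config(seed=11)))


@pytest.fixture(scope="session")
def noisy_sim():
    """Small simulation with the full error machinery."""
    return simulate_all(small_config(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
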