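"""Shared fixtures: small smoke-scale study runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import indentml as m
from indentml.benchmark import SMOKE_SCALE, run_model_study


@pytest.fixture(scope="session")
def smoke_nh() -> dict:
    """Small neo-Hookean pipeline: data, trained nets, inversion summaries."""
    return run_model_study("neo_hookean", seed=1, scale=SMOKE_SCALE)


@pytest.fixture(scope="session")
def smoke_gent() -> dict:
    """Small Gent pipeline."""
    return run_model_study("gent", seed=1, scale=SMOKE_SCALE)


@pytest.fixture(scope="session")
def nh_dataset_small():
    """A 200/50/50 neo-Hookean dataset triple (no training)."""
    return m.build_dataset(sizes=(200, 50, 50))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
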