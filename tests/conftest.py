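"""Shared fixtures: one small synthetic dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ecgtb.features import feature_table
from ecgtb.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_segments():
    """A small but class-complete synthetic dataset (25 segments)."""
    return generate_dataset({"Norm": 10, "AF": 6, "PVC": 5, "APB": 4}, seed=7)


@pytest.fixture(scope="session")
def small_table(small_segments):
    return feature_table(small_segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
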