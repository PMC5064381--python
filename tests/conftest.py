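from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctcflow import SyntheticSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A compact mixed scene: in-gate cells, sub-gate cells and debris."""
    return SyntheticSpec(n_cells=5, n_debris=2, n_small_cells=2, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
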