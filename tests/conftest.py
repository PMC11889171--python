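"""Shared fixtures: small synthetic lamella datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibdamage import SyntheticConfig, build_fixture_bundle
from fibdamage.surface_geometry import SurfaceSheet


SMALL_CONFIG = dict(
    n_tomograms=6,
    particles_per_tomogram=4200,
    tomo_shape=(256, 256, 386),
    seed=7,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    """A compact fixture bundle shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("bundle")
    build_fixture_bundle(small_config, out)
    return out


@pytest.fixture
def planar_sheets():
    """Parallel planar sheets 200 nm apart at 10 A/px (20 voxels)."""
    grid = np.full((30, 30), 100.0)
    front = SurfaceSheet(grid.copy(), 0.0, 0.0, 10.0, role="front")
    back = SurfaceSheet(grid + 200.0, 0.0, 0.0, 10.0, role="back")
    return front, back


@pytest.fixture
def depth_frame():
    """Hand-built particle frame with depths for cohort tests."""
    rng = np.random.default_rng(42)
    n = 3000
    tomos = rng.choice([f"t{i}" for i in range(5)], size=n)
    depth = rng.uniform(0, 100, size=n)
    return pd.DataFrame(
        {
            "particle_id": [f"p{i}" for i in range(n)],
            "tomogram_id": tomos,
            "x": rng.uniform(0, 256, n),
            "y": rng.uniform(0, 256, n),
            "z": rng.uniform(0, 386, n),
            "depth_nm": depth,
            "inside": True,
        }
    )
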