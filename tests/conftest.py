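"""Shared fixtures: small geometries and synthetic scan data.

Everything is generated programmatically; no binary fixtures on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import acoct as a


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture()
def par16() -> a.ScanGeometry:
    # start angle avoids axis-aligned rays sitting exactly on voxel planes
    return a.parallel_geometry(n=16, n_views=10, span=360.0, start=3.7)


@pytest.fixture()
def fan16() -> a.ScanGeometry:
    return a.fan_geometry(n=16, n_views=10, span=360.0, start=3.7)


@pytest.fixture(scope="session")
def phantom32() -> a.ImageVolume:
    return a.render_phantom(a.thorax_like_spec((32, 32)), voxel_size=1.0)


@pytest.fixture(scope="session")
def scan32(phantom32) -> tuple[a.ImageVolume, a.ScanGeometry, a.ProjectionSet]:
    """Noiseless 32x32 fan-beam scan with 50 views."""
    geom = a.fan_geometry(n=32, n_views=50)
    b = a.forward_project(phantom32, geom)
    return phantom32, geom, b


@pytest.fixture(scope="session")
def noisy32(scan32) -> tuple[a.ImageVolume, a.ScanGeometry, a.ProjectionSet]:
    truth, geom, b = scan32
    noisy = a.add_ct_noise(b, a.NoiseModel(seed=11))
    return truth, geom, noisy
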