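"""Shared fixtures: small meshes and populations, all generated in memory."""

from __future__ import annotations

import numpy as np
import pytest

from diffcentroid.kernels import KernelConfig
from diffcentroid.matching import MatchConfig
from diffcentroid.mesh_io import TriangleMesh
from diffcentroid.synthetic import SyntheticConfig, generate_population, make_base_shape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sphere12() -> TriangleMesh:
    """Level-0 icosphere: 12 vertices, 20 faces, radius 10 mm."""
    return make_base_shape(12, "icosphere")


@pytest.fixture(scope="session")
def sphere42() -> TriangleMesh:
    """Level-1 icosphere: 42 vertices, 80 faces."""
    return make_base_shape(42, "icosphere")


@pytest.fixture(scope="session")
def base162() -> TriangleMesh:
    """The default 162-vertex bent-ellipsoid base shape."""
    return make_base_shape(162, "bent_ellipsoid")


@pytest.fixture(scope="session")
def kV() -> KernelConfig:
    return KernelConfig("cauchy", 15.0)


@pytest.fixture(scope="session")
def match_cfg(kV) -> MatchConfig:
    return MatchConfig(kernel_V=kV, kernel_W=KernelConfig("cauchy", 7.5))


@pytest.fixture(scope="session")
def small_match_cfg(kV) -> MatchConfig:
    """Cheaper matcher for many-matching tests on small meshes."""
    return MatchConfig(
        kernel_V=kV, kernel_W=KernelConfig("cauchy", 7.5), max_iter=60
    )


@pytest.fixture(scope="session")
def tiny_population(sphere42, kV):
    """Six 42-vertex subjects around a known exact centre."""
    cfg = SyntheticConfig(
        n_subjects=6, base_shape=sphere42, kernel_V=kV, seed=7
    )
    return generate_population(cfg)


def tetrahedron() -> TriangleMesh:
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(verts, faces, name="tetra")


@pytest.fixture
def tetra() -> TriangleMesh:
    return tetrahedron()
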