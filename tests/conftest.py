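"""Shared fixtures: toy meshes for linear-algebra oracles, a small synthetic
jaw bundle, and the session-wide seeded detection experiment."""

from __future__ import annotations

import numpy as np
import pytest

from shapedent.mesh_core import TriangleMesh
from shapedent.pipeline import run_detection_experiment
from shapedent.shape_model import build_pca_model
from shapedent.synthetic_jaw import JawParams, generate_reference_jaw

# one seed drives every stochastic fixture in the suite
SUITE_SEED = 20260925


def make_quad_mesh() -> TriangleMesh:
    """A 4-vertex, 2-triangle planar patch used by the dense oracles."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0]]
    )
    triangles = np.array([[0, 1, 2], [1, 3, 2]])
    return TriangleMesh(vertices, triangles)


def make_grid_mesh(nu: int, nv: int, spacing: float = 1.0) -> TriangleMesh:
    """A planar nu x nv grid strip, handy when 1-ring adjacency matters."""
    ii, jj = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    vertices = np.stack(
        [ii.ravel() * spacing, jj.ravel() * spacing, np.zeros(nu * nv)], axis=1
    )
    i, j = np.meshgrid(np.arange(nu - 1), np.arange(nv - 1), indexing="ij")
    v00 = i * nv + j
    tris = np.vstack(
        [
            np.stack([v00, v00 + nv, v00 + 1], axis=-1).reshape(-1, 3),
            np.stack([v00 + 1, v00 + nv, v00 + nv + 1], axis=-1).reshape(-1, 3),
        ]
    )
    return TriangleMesh(vertices, tris)


def make_displaced_cohort(
    base: TriangleMesh, n: int, scale: float = 0.1, seed: int = SUITE_SEED
) -> list[TriangleMesh]:
    """Meshes in correspondence with random vertex displacements."""
    rng = np.random.default_rng(seed)
    return [
        base.with_vertices(base.vertices + scale * rng.standard_normal(base.vertices.shape))
        for _ in range(n)
    ]


@pytest.fixture()
def quad_mesh() -> TriangleMesh:
    return make_quad_mesh()


@pytest.fixture()
def toy_model():
    """Rank-4 model over the quad patch, built from 5 displaced copies."""
    base = make_quad_mesh()
    return build_pca_model(make_displaced_cohort(base, 5))


@pytest.fixture(scope="session")
def jaw_bundle():
    """(reference mesh, tooth regions, landmark set) at default parameters."""
    return generate_reference_jaw(JawParams())


@pytest.fixture(scope="session")
def jaw_model():
    """Kernel-augmented PCA model from a 9-jaw synthetic cohort."""
    from shapedent.pipeline import build_model_from_cohort

    return build_model_from_cohort(
        JawParams(), 9, 1.0, seed=SUITE_SEED,
        kernel_variance=4.0, kernel_bandwidth=40.0, extra_rank=50,
    )


@pytest.fixture(scope="session")
def detection_experiment():
    """The full seeded pipeline experiment (model building, 30 corrupted
    targets, robust fits, detection, scoring). Shared across tests because
    it is by far the most expensive fixture."""
    return run_detection_experiment(seed=1)
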