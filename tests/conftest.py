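"""Shared fixtures: analytic test surfaces and the synthetic-study datasets."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from woundshape import (
    GeneratorConfig,
    HistogramSpec,
    TriangleMesh,
    base_grid_mesh,
    featurize_meshes,
    generate_dataset,
)


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    """Unit sphere tessellation with outward normals (analytic mc = +1)."""
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriangleMesh(
        np.asarray(ico.vertices), np.asarray(ico.faces), frame_tag="normalized"
    )


@pytest.fixture(scope="session")
def flat_grid() -> TriangleMesh:
    """Flat unit-square grid in the normalized frame (mc = K = 0)."""
    mesh = base_grid_mesh(GeneratorConfig(resolution=30, side_mm=1.0))
    return TriangleMesh(
        mesh.vertices - mesh.vertices.mean(axis=0), mesh.faces, frame_tag="normalized"
    )


@pytest.fixture(scope="session")
def saddle_grid() -> TriangleMesh:
    """Grid sampling of z = x^2 - y^2 (hyperbolic everywhere, K < 0)."""
    n = 41
    c = np.linspace(-0.5, 0.5, n)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    V = np.column_stack([xx.ravel(), yy.ravel(), (xx**2 - yy**2).ravel()])
    faces = base_grid_mesh(GeneratorConfig(resolution=n, side_mm=1.0)).faces
    return TriangleMesh(V, faces, frame_tag="normalized")


def tube_mesh(radius: float, height: float = 4.0, n_ring: int = 64, n_h: int = 24):
    """Open cylinder tube (no caps); interior vertices have mc = 1/(2r)."""
    zs = np.linspace(-height / 2, height / 2, n_h)
    phis = np.arange(n_ring) * 2 * np.pi / n_ring
    V = np.array(
        [
            (radius * np.cos(p), radius * np.sin(p), z)
            for z in zs
            for p in phis
        ]
    )
    faces = []
    for i in range(n_h - 1):
        for j in range(n_ring):
            a = i * n_ring + j
            b = i * n_ring + (j + 1) % n_ring
            c = a + n_ring
            d = b + n_ring
            faces.append((a, b, d))
            faces.append((a, d, c))
    return TriangleMesh(V, np.array(faces), frame_tag="normalized")


@pytest.fixture(scope="session")
def surrogate_runs() -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Featurized default synthetic datasets for three master seeds.

    Shared across the end-to-end tests because generation + featurization
    dominates their cost.
    """
    runs = {}
    for seed in (1, 2, 3):
        meshes, labels = generate_dataset(GeneratorConfig(master_seed=seed))
        X = featurize_meshes(
            meshes, HistogramSpec(seed=seed), mesh_ids=list(labels["mesh_id"])
        )
        runs[seed] = (X, labels["class"].to_numpy())
    return runs
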