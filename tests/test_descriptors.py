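"""Descriptor blocks against hand-enumerated oracles; shape-vector structure."""

import numpy as np
import pytest

from woundshape import (
    GeneratorConfig,
    HistogramSpec,
    TriangleMesh,
    assemble_shape_vector,
    base_grid_mesh,
    estimate_curvature,
    normalize_to_unit_square,
)
from woundshape.descriptors import (
    N_DESCRIPTORS,
    SHAPE_VECTOR_LEN,
    concentric_sphere_counts,
    convex_hull_measures,
    count_hyperbolic,
    distance_histogram,
    fourier_magnitudes,
    scalar_descriptors,
)


class TestDistanceHistogram:
    def test_three_collinear_points(self):
        # distances {1, 1, 2}; bin width 0.05 -> bin 20 twice, last bin once
        h, d = distance_histogram(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        assert h[20] == 2
        assert h[39] == 1
        assert h.sum() == 3
        assert sorted(d) == [1, 1, 2]

    def test_single_point_all_zero(self):
        h, d = distance_histogram(np.array([[0.3, 0.1, 0.0]]))
        assert np.all(h == 0)
        assert len(d) == 0

    def test_half_open_bins(self):
        # 0.51 / 0.05 = 10.2 -> bin 10
        h, _ = distance_histogram(np.array([[0, 0, 0], [0.51, 0, 0]]))
        assert h[10] == 1
        assert h.sum() == 1

    def test_distances_beyond_range_clip_into_last_bin(self):
        h, _ = distance_histogram(np.array([[0, 0, 0], [5, 0, 0]], float))
        assert h[39] == 1

    def test_subsample_cap_is_seeded(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        spec = HistogramSpec(subsample_cap=20, seed=5)
        h1, _ = distance_histogram(pts, spec)
        h2, _ = distance_histogram(pts, spec)
        np.testing.assert_array_equal(h1, h2)
        assert h1.sum() == 20 * 19 / 2


class TestScalarDescriptors:
    def test_ratio_descriptors(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        h, d = distance_histogram(pts)
        d40, d41, d44, d45 = scalar_descriptors(pts, h, d, 3)
        assert d40 == pytest.approx(2 / (4 / 3))  # max/mean = 1.5
        assert d41 == pytest.approx(2.0)  # max/median
        assert d44 == pytest.approx(2 / (3 / 40))  # max freq / mean freq
        assert d45 == 3

    def test_fewer_than_two_points(self):
        h = np.zeros(40)
        assert scalar_descriptors(np.zeros((1, 3)), h, np.empty(0), 1) == (0, 0, 0, 1)


class TestConvexHull:
    def test_unit_cube(self):
        pts = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float
        )
        vol, area = convex_hull_measures(pts)
        assert vol == pytest.approx(1.0)
        assert area == pytest.approx(6.0)

    def test_regular_tetrahedron_edge_one(self):
        pts = np.array(
            [
                [0, 0, 0],
                [1, 0, 0],
                [0.5, np.sqrt(3) / 2, 0],
                [0.5, np.sqrt(3) / 6, np.sqrt(2 / 3)],
            ]
        )
        vol, area = convex_hull_measures(pts)
        assert vol == pytest.approx(1 / (6 * np.sqrt(2)))
        assert area == pytest.approx(np.sqrt(3))

    @pytest.mark.parametrize(
        "pts",
        [
            np.zeros((3, 3)),  # fewer than 4 points
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float),  # coplanar
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float),  # collinear
        ],
    )
    def test_degenerate_inputs_give_zero(self, pts):
        assert convex_hull_measures(pts) == (0.0, 0.0)


class TestConcentricSpheres:
    def test_hand_thresholding(self):
        pts = np.array([[0.05, 0, 0], [0.35, 0, 0], [0.55, 0, 0], [0.95, 0, 0]])
        counts = concentric_sphere_counts(pts, r_ref=1.0)
        np.testing.assert_array_equal(counts, [1, 1, 1, 2, 2, 3, 3, 3, 3, 4])

    def test_all_points_at_origin(self):
        counts = concentric_sphere_counts(np.zeros((7, 3)), r_ref=1.0)
        np.testing.assert_array_equal(counts, np.full(10, 7))

    def test_empty_subset(self):
        np.testing.assert_array_equal(
            concentric_sphere_counts(np.empty((0, 3)), 1.0), np.zeros(10)
        )


class TestFourier:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ([1, 1, 1, 1], [4, 0, 0, 0]),
            ([1, 0, 0, 0], [1, 1, 1, 1]),
            ([0, 1, 0, -1], [0, 2, 0, 2]),
        ],
    )
    def test_hand_dft(self, seq, expected):
        np.testing.assert_allclose(fourier_magnitudes(seq), expected, atol=1e-12)


class TestHyperbolicCount:
    def test_saddle_interior_all_hyperbolic(self, saddle_grid):
        field = estimate_curvature(saddle_grid)
        interior = np.flatnonzero(~field.boundary)
        assert count_hyperbolic(interior, field) == len(interior)

    def test_sphere_has_none(self, icosphere):
        field = estimate_curvature(icosphere)
        assert count_hyperbolic(np.arange(len(field)), field) == 0

    def test_empty_subset(self, icosphere):
        field = estimate_curvature(icosphere)
        assert count_hyperbolic(np.array([], int), field) == 0


@pytest.fixture(scope="module")
def lesion_vector():
    from woundshape import deform
    from woundshape.synthetic import DEFAULT_CLASS_SPECS, InjuryClass

    base = base_grid_mesh(GeneratorConfig(resolution=60))
    mesh = deform(base, DEFAULT_CLASS_SPECS[InjuryClass.GUNSHOT], seed=3)
    norm, _ = normalize_to_unit_square(mesh)
    return norm, assemble_shape_vector(norm, HistogramSpec(seed=0))


class TestShapeVector:

    def test_length_and_block_structure(self, lesion_vector):
        _, sv = lesion_vector
        assert sv.values.shape == (SHAPE_VECTOR_LEN,)
        assert SHAPE_VECTOR_LEN == 12 * 107
        for n in range(12):
            assert len(sv.block(n)) == N_DESCRIPTORS

    def test_flat_mesh_gives_all_zero_vector(self, flat_grid):
        sv = assemble_shape_vector(flat_grid, HistogramSpec(seed=0))
        assert np.all(sv.values == 0)

    def test_deterministic(self, lesion_vector):
        norm, sv = lesion_vector
        again = assemble_shape_vector(norm, HistogramSpec(seed=0))
        np.testing.assert_array_equal(sv.values, again.values)

    def test_histogram_mass_and_sphere_invariants(self, lesion_vector):
        _, sv = lesion_vector
        cap = HistogramSpec().subsample_cap
        for n in range(12):
            block = sv.block(n)
            size = sv.subset_sizes[f"S_{n}"]
            used = min(size, cap)
            assert block[0:40].sum() == used * (used - 1) / 2
            spheres = block[46:56]
            assert np.all(np.diff(spheres) >= 0)
            assert spheres[-1] == size  # all points inside the outermost sphere
            # DC terms of both spectra equal the sums of their inputs
            assert block[56] == pytest.approx(block[0:40].sum())
            assert block[96] == pytest.approx(spheres.sum())
            assert block[45] == size

    def test_rotation_invariance_about_z(self):
        from woundshape import deform
        from woundshape.synthetic import DEFAULT_CLASS_SPECS, InjuryClass

        spec = DEFAULT_CLASS_SPECS[InjuryClass.GUNSHOT]
        base = base_grid_mesh(GeneratorConfig(resolution=60))
        mesh = deform(base, spec, seed=11)
        theta = np.pi / 2  # exact lattice rotation keeps sampling identical
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = TriangleMesh((mesh.vertices - mesh.vertices.mean(0)) @ R.T, mesh.faces)
        sv1 = assemble_shape_vector(
            normalize_to_unit_square(mesh)[0], HistogramSpec(seed=0)
        )
        sv2 = assemble_shape_vector(
            normalize_to_unit_square(rotated)[0], HistogramSpec(seed=0)
        )
        np.testing.assert_allclose(sv1.values, sv2.values, atol=1e-4, rtol=1e-4)
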