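"""The 107-element descriptor block per curvature subset and the 1284 shape vector.

For each of the 12 non-flat curvature subsets S_0..S_11 the following
descriptors are computed, in this fixed order:

====== ====================================================================
index  meaning
====== ====================================================================
d0-39   inter-vertex Euclidean distance histogram, 40 equal bins on [0, 2]
d40     max / mean pairwise distance
d41     max / median pairwise distance
d42     convex-hull volume of the subset's vertices
d43     convex-hull surface area
d44     max / mean histogram frequency
d45     number of vertices in the subset (before any subsampling)
d46-55  cumulative vertex counts inside 10 concentric spheres around the
        origin, radii j*R/10 with R the max vertex norm of the whole mesh
d56-95  DFT magnitudes of the distance histogram (DC first)
d96-105 DFT magnitudes of the sphere-count series
d106    number of hyperbolic (saddle, K < 0) vertices
====== ====================================================================

Concatenating the 12 blocks gives the 12 x 107 = 1284 element shape vector.
Empty subsets contribute all-zero blocks so every mesh maps to the same
rectangular feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .curvature import (
    SUBSET_LABELS,
    CurvatureField,
    FLAT_THRESHOLD_DEFAULT,
    SubsetPartition,
    estimate_curvature,
    partition_by_curvature,
)
from .mesh import MeshError, TriangleMesh

N_DESCRIPTORS = 107
N_SUBSETS = 12
SHAPE_VECTOR_LEN = N_SUBSETS * N_DESCRIPTORS  # 1284

#: column names for serialized shape vectors: s{n}_d{i}
COLUMN_NAMES = tuple(
    f"s{n}_d{i}" for n in range(N_SUBSETS) for i in range(N_DESCRIPTORS)
)


@dataclass
class HistogramSpec:
    """Parameters of the distance histogram and subset subsampling.

    The bin range is fixed at [0, 2] in normalized units (the diameter of
    the unit square's circumscribing circle is sqrt(2) < 2, but z-relief can
    push pairwise distances slightly beyond; anything above ``r_max`` is
    clipped into the last bin).  A seeded uniform subsample caps the O(n^2)
    all-pairs cost for large subsets.
    """

    bin_count: int = 40
    r_max: float = 2.0
    subsample_cap: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


def distance_histogram(
    points: np.ndarray, spec: HistogramSpec | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise Euclidean distances.

    Bins are half-open ``[k*w, (k+1)*w)`` with ``w = r_max / bin_count``;
    the last bin is closed and also receives clipped distances > r_max.
    Returns ``(counts, distances)`` where ``distances`` are the (possibly
    subsampled) pairwise distances actually binned — callers reuse them for
    the ratio descriptors.  Fewer than 2 points yields all zeros.
    """
    spec = spec or HistogramSpec()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) > spec.subsample_cap:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        keep = rng.choice(len(points), size=spec.subsample_cap, replace=False)
        points = points[np.sort(keep)]
    if len(points) < 2:
        return np.zeros(spec.bin_count), np.empty(0)
    d = pdist(points)
    edges = np.linspace(0.0, spec.r_max, spec.bin_count + 1)
    counts, _ = np.histogram(np.minimum(d, spec.r_max), bins=edges)
    return counts.astype(float), d


def scalar_descriptors(
    points: np.ndarray, histogram: np.ndarray, distances: np.ndarray, true_size: int
) -> tuple[float, float, float, float]:
    """d40, d41, d44, d45 from the (subsampled) distances and histogram.

    ``true_size`` is the subset size before subsampling; it is what d45
    reports.  With fewer than 2 points the three ratios are 0.
    """
    if len(distances) < 1:
        return 0.0, 0.0, 0.0, float(true_size)
    dmax = float(distances.max())
    d40 = dmax / float(distances.mean())
    d41 = dmax / float(np.median(distances))
    mean_freq = float(histogram.mean())
    d44 = float(histogram.max()) / mean_freq if mean_freq > 0 else 0.0
    return d40, d41, d44, float(true_size)


def convex_hull_measures(points: np.ndarray) -> tuple[float, float]:
    """3D convex-hull volume (d42) and total facet surface area (d43).

    Degenerate inputs — fewer than 4 points, or coplanar/collinear sets —
    are a defined result of (0, 0), not an error.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 4:
        return 0.0, 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, 0.0
    return float(hull.volume), float(hull.area)


def concentric_sphere_counts(
    points: np.ndarray, r_ref: float, sphere_count: int = 10
) -> np.ndarray:
    """Cumulative counts of subset points inside concentric origin spheres.

    Radii are ``r_j = j * r_ref / sphere_count`` for j = 1..sphere_count,
    where ``r_ref`` is the maximum vertex norm over the *whole* normalized
    mesh — so the outermost sphere encloses every vertex and the series is
    non-decreasing with last value = |subset|.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(sphere_count)
    norms = np.linalg.norm(points, axis=1)
    radii = np.arange(1, sphere_count + 1) * (r_ref / sphere_count)
    return (norms[None, :] <= radii[:, None]).sum(axis=1).astype(float)


def fourier_magnitudes(sequence: np.ndarray) -> np.ndarray:
    """Magnitudes of the DFT of ``sequence``, DC term first, same length."""
    return np.abs(np.fft.fft(np.asarray(sequence, dtype=float)))


def count_hyperbolic(indices: np.ndarray, field: CurvatureField) -> int:
    """d106: number of subset vertices with negative Gaussian curvature."""
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return 0
    return int(np.count_nonzero(field.gaussian[indices] < 0.0))


@dataclass
class ShapeVector:
    """Ordered 1284-element descriptor vector for one mesh."""

    values: np.ndarray  # (1284,)
    mesh_id: str = ""
    subset_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (SHAPE_VECTOR_LEN,):
            raise ValueError(f"shape vector must have length {SHAPE_VECTOR_LEN}")

    def block(self, subset: int) -> np.ndarray:
        """The 107-descriptor block of subset ``S_subset``."""
        return self.values[subset * N_DESCRIPTORS : (subset + 1) * N_DESCRIPTORS]


def subset_descriptors(
    points: np.ndarray,
    indices: np.ndarray,
    field: CurvatureField,
    r_ref: float,
    spec: HistogramSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The 107 descriptors of one curvature subset."""
    hist, dists = distance_histogram(points, spec, rng=rng)
    d40, d41, d44, d45 = scalar_descriptors(points, hist, dists, len(points))
    d42, d43 = convex_hull_measures(points)
    spheres = concentric_sphere_counts(points, r_ref)
    out = np.empty(N_DESCRIPTORS)
    out[0:40] = hist
    out[40:46] = (d40, d41, d42, d43, d44, d45)
    out[46:56] = spheres
    out[56:96] = fourier_magnitudes(hist)
    out[96:106] = fourier_magnitudes(spheres)
    out[106] = count_hyperbolic(indices, field)
    return out


def assemble_shape_vector(
    mesh: TriangleMesh,
    spec: HistogramSpec | None = None,
    threshold_flat: float = FLAT_THRESHOLD_DEFAULT,
    mesh_id: str = "",
    weighting: str = "voronoi",
    field_partition: tuple[CurvatureField, SubsetPartition] | None = None,
) -> ShapeVector:
    """Curvature -> partition -> per-subset descriptors -> 1284 vector.

    The flat subset S_f is discarded; empty subsets contribute zero blocks.
    Deterministic for a fixed ``spec.seed`` (subsampling draws use a child
    seed per subset).
    """
    if mesh.frame_tag != "normalized":
        raise MeshError("shape vectors are computed on normalized meshes")
    spec = spec or HistogramSpec()
    if field_partition is None:
        fld = estimate_curvature(mesh, weighting=weighting)
        part = partition_by_curvature(fld, threshold_flat)
    else:
        fld, part = field_partition
    r_ref = float(np.linalg.norm(mesh.vertices, axis=1).max())
    values = np.zeros(SHAPE_VECTOR_LEN)
    sizes: dict[str, int] = {}
    for n, label in enumerate(SUBSET_LABELS):
        idx = part.subsets[label]
        sizes[label] = len(idx)
        if len(idx) == 0:
            continue
        rng = np.random.default_rng([spec.seed, n])
        values[n * N_DESCRIPTORS : (n + 1) * N_DESCRIPTORS] = subset_descriptors(
            mesh.vertices[idx], idx, fld, r_ref, spec, rng=rng
        )
    return ShapeVector(values=values, mesh_id=mesh_id, subset_sizes=sizes)


def featurize_meshes(
    meshes: list[TriangleMesh],
    spec: HistogramSpec | None = None,
    mesh_ids: list[str] | None = None,
) -> np.ndarray:
    """Stack shape vectors of many meshes into an (n_meshes, 1284) matrix.

    Raw-frame meshes are normalized on the fly.
    """
    from .mesh import normalize_to_unit_square

    rows = []
    for i, m in enumerate(meshes):
        if m.frame_tag == "raw":
            m, _ = normalize_to_unit_square(m)
        mid = mesh_ids[i] if mesh_ids else str(i)
        rows.append(assemble_shape_vector(m, spec, mesh_id=mid).values)
    return np.vstack(rows)
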