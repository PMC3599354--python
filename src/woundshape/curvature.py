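"""Per-vertex curvature estimation and partition into mean-curvature bands.

Curvature is estimated with the per-face Weingarten (second fundamental
form) approach: for every triangle a 2x2 symmetric curvature tensor is fit
by least squares to the variation of the vertex normals along the three
edges, and the face tensors are then averaged onto the vertices in each
vertex's own tangent frame, weighted by the face's mixed-Voronoi area
contribution at that corner.  Principal curvatures are the eigenvalues of
the averaged tensor.

Sign convention: positive mean curvature = locally convex (a bump seen from
the side the normals point to); a unit sphere with outward normals has
mc = +1.  Curvature is computed in the normalized (unit-square) frame so the
fixed band thresholds below are comparable across specimens.

The 13 bands: one flat band S_f = {|mc| <= threshold_flat} that is discarded
from descriptor computation, six convex bands S_0..S_5 (strongly convex to
little convex) and six concave bands S_6..S_11.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshError, TriangleMesh

FLAT_THRESHOLD_DEFAULT = 0.17

#: subset labels in shape-vector order; S_f is the discarded flat band
SUBSET_LABELS = tuple(f"S_{n}" for n in range(12))


class OrientationError(MeshError):
    """Face windings are not globally consistent; normals would flip."""


class CurvatureDataError(ValueError):
    """Non-finite curvature value encountered."""


@dataclass
class CurvatureField:
    """Per-vertex curvature values on one mesh."""

    kappa1: np.ndarray  # larger principal curvature
    kappa2: np.ndarray  # smaller principal curvature
    mean: np.ndarray  # (kappa1 + kappa2) / 2
    gaussian: np.ndarray  # kappa1 * kappa2
    boundary: np.ndarray  # bool flag, estimate used one-sided neighborhood

    @property
    def hyperbolic(self) -> np.ndarray:
        """Saddle points: principal curvatures of opposite sign (K < 0)."""
        return self.gaussian < 0.0

    def __len__(self) -> int:
        return len(self.mean)


@dataclass
class SubsetPartition:
    """Assignment of every vertex to exactly one of the 13 curvature bands."""

    flat: np.ndarray  # vertex indices in S_f
    subsets: dict[str, np.ndarray]  # label -> vertex indices, S_0..S_11
    threshold_flat: float

    def sizes(self) -> dict[str, int]:
        out = {"S_f": len(self.flat)}
        out.update({k: len(v) for k, v in self.subsets.items()})
        return out


def _check_orientation(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    """Verify globally consistent winding; return boundary-vertex mask."""
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = directed[:, 0].astype(np.int64) * n_vertices + directed[:, 1]
    if len(np.unique(key)) != len(key):
        # an interior edge traversed twice in the same direction means the
        # two incident faces disagree on orientation
        raise OrientationError("inconsistent face orientation (duplicate directed edge)")
    undirected = np.sort(directed, axis=1)
    ukey = undirected[:, 0].astype(np.int64) * n_vertices + undirected[:, 1]
    uniq, counts = np.unique(ukey, return_counts=True)
    boundary_edges = uniq[counts == 1]
    boundary = np.zeros(n_vertices, dtype=bool)
    boundary[(boundary_edges // n_vertices)] = True
    boundary[(boundary_edges % n_vertices)] = True
    return boundary


def _mixed_voronoi_corner_areas(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """(m, 3) mixed-Voronoi area contribution of each face at each corner.

    Non-obtuse triangles use the circumcentric (cotangent) Voronoi split;
    obtuse triangles fall back to area/2 at the obtuse corner and area/4 at
    the other two (Meyer's mixed-area rule), which keeps areas positive.
    """
    p = V[F]  # (m, 3, 3)
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    # edge e[:, i] is opposite corner i
    l2 = np.einsum("mij,mij->mi", e, e)
    area = 0.5 * np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)
    area = np.maximum(area, 1e-300)
    # cot of angle at corner i relates the two edges adjacent to corner i
    cot = np.empty_like(l2)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        cot[:, i] = np.einsum("mi,mi->m", -e[:, j], e[:, k]) / (2.0 * area)
    corner = np.empty_like(l2)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        corner[:, i] = (l2[:, j] * cot[:, j] + l2[:, k] * cot[:, k]) / 8.0
    obtuse = cot < 0.0
    any_obtuse = obtuse.any(axis=1)
    if any_obtuse.any():
        idx = np.where(any_obtuse)[0]
        corner[idx] = area[idx, None] / 4.0
        which = np.argmax(obtuse[idx], axis=1)
        corner[idx, which] = area[idx] / 2.0
    return corner


def estimate_curvature(
    mesh: TriangleMesh, weighting: str = "voronoi"
) -> CurvatureField:
    """Estimate per-vertex principal/mean/Gaussian curvature.

    Parameters
    ----------
    mesh
        Normalized-frame mesh with globally consistent face orientation.
    weighting
        ``"voronoi"`` (default) weights each face's tensor by its
        mixed-Voronoi area contribution at the vertex; ``"uniform"`` uses
        one third of the face area at every corner.
    """
    if mesh.frame_tag != "normalized":
        raise MeshError("curvature is estimated in the normalized frame")
    if weighting not in ("voronoi", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    V, F = mesh.vertices, mesh.faces
    boundary = _check_orientation(F, len(V))

    p = V[F]
    e0 = p[:, 1] - p[:, 0]
    e1 = p[:, 2] - p[:, 0]
    fn = np.cross(e0, e1)
    fa2 = np.linalg.norm(fn, axis=1)
    fa2 = np.maximum(fa2, 1e-300)
    fn = fn / fa2[:, None]
    face_area = 0.5 * fa2

    # angle-weighted vertex normals
    vn = np.zeros_like(V)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        a = p[:, j] - p[:, i]
        b = p[:, k] - p[:, i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip(
            np.einsum("mi,mi->m", a, b) / np.maximum(na * nb, 1e-300), -1.0, 1.0
        )
        ang = np.arccos(cosang)
        np.add.at(vn, F[:, i], fn * ang[:, None])
    norms = np.linalg.norm(vn, axis=1)
    vn = vn / np.maximum(norms, 1e-300)[:, None]

    # per-face orthonormal tangent frame (u, v)
    u = e0 / np.maximum(np.linalg.norm(e0, axis=1), 1e-300)[:, None]
    v = np.cross(fn, u)

    # least squares for the symmetric tensor W = [[a, b], [b, c]] with
    # W [e.u, e.v]^T = [dn.u, dn.v]^T over the three edges
    edges = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    n_corner = vn[F]
    dns = np.stack(
        [n_corner[:, 2] - n_corner[:, 1], n_corner[:, 0] - n_corner[:, 2],
         n_corner[:, 1] - n_corner[:, 0]],
        axis=1,
    )
    eu = np.einsum("mij,mj->mi", edges, u)
    ev = np.einsum("mij,mj->mi", edges, v)
    du = np.einsum("mij,mj->mi", dns, u)
    dv = np.einsum("mij,mj->mi", dns, v)
    m = len(F)
    A = np.zeros((m, 6, 3))
    rhs = np.zeros((m, 6))
    A[:, 0:3, 0] = eu
    A[:, 0:3, 1] = ev
    A[:, 3:6, 1] = eu
    A[:, 3:6, 2] = ev
    rhs[:, 0:3] = du
    rhs[:, 3:6] = dv
    AtA = np.einsum("mri,mrj->mij", A, A)
    AtA += 1e-12 * np.eye(3)
    Atb = np.einsum("mri,mr->mi", A, rhs)
    W = np.linalg.solve(AtA, Atb[..., None])[..., 0]  # (m, 3): a, b, c per face

    if weighting == "voronoi":
        corner_w = _mixed_voronoi_corner_areas(V, F)
    else:
        corner_w = np.repeat(face_area[:, None] / 3.0, 3, axis=1)

    # accumulate face tensors into each vertex's own tangent frame
    acc = np.zeros((len(V), 3))
    wsum = np.zeros(len(V))
    for i in range(3):
        vid = F[:, i]
        nv = vn[vid]
        # rotate the vertex frame into the face plane: rotation taking nv -> fn
        axis = np.cross(nv, fn)
        c = np.einsum("mi,mi->m", nv, fn)
        ok = c > -0.9999
        # vertex tangent basis (up, vp) orthogonal to nv
        ref = np.zeros_like(nv)
        small = np.abs(nv[:, 0]) < 0.9
        ref[small, 0] = 1.0
        ref[~small, 1] = 1.0
        up = np.cross(nv, ref)
        up /= np.maximum(np.linalg.norm(up, axis=1), 1e-300)[:, None]
        vp = np.cross(nv, up)

        def rotate(w):
            # Rodrigues with unnormalized axis = nv x fn, |axis| = sin
            cross1 = np.cross(axis, w)
            cross2 = np.cross(axis, cross1)
            return w + cross1 + cross2 / np.maximum(1.0 + c, 1e-12)[:, None]

        upf = rotate(up)
        vpf = rotate(vp)
        # components of the rotated basis in the face (u, v) frame
        upu = np.einsum("mi,mi->m", upf, u)
        upv = np.einsum("mi,mi->m", upf, v)
        vpu = np.einsum("mi,mi->m", vpf, u)
        vpv = np.einsum("mi,mi->m", vpf, v)
        a_f, b_f, c_f = W[:, 0], W[:, 1], W[:, 2]

        def quad(x1, y1, x2, y2):
            return a_f * x1 * x2 + b_f * (x1 * y2 + y1 * x2) + c_f * y1 * y2

        new_a = quad(upu, upv, upu, upv)
        new_b = quad(upu, upv, vpu, vpv)
        new_c = quad(vpu, vpv, vpu, vpv)
        wgt = corner_w[:, i] * ok
        np.add.at(acc, vid, np.stack([new_a * wgt, new_b * wgt, new_c * wgt], axis=1))
        np.add.at(wsum, vid, wgt)

    wsum = np.maximum(wsum, 1e-300)
    a, b, c = (acc[:, k] / wsum for k in range(3))
    h = 0.5 * (a + c)
    d = np.sqrt(np.maximum(0.25 * (a - c) ** 2 + b**2, 0.0))
    kappa1 = h + d
    kappa2 = h - d
    return CurvatureField(
        kappa1=kappa1,
        kappa2=kappa2,
        mean=h,
        gaussian=kappa1 * kappa2,
        boundary=boundary,
    )


# band edges for the convex side, mirrored for the concave side; the flat
# band |mc| <= threshold_flat overrides the innermost edges and wins ties
_CONVEX_EDGES = (0.8, 0.6, 0.5, 0.4, 0.25)


def partition_by_curvature(
    field: CurvatureField, threshold_flat: float = FLAT_THRESHOLD_DEFAULT
) -> SubsetPartition:
    """Assign every vertex to exactly one of the 13 mean-curvature bands.

    Convex bands (half-open, upper edge inclusive):
    S_0: mc > 0.8, S_1: 0.6 < mc <= 0.8, S_2: 0.5 < mc <= 0.6,
    S_3: 0.4 < mc <= 0.5, S_4: 0.25 < mc <= 0.4, S_5: t < mc <= 0.25.
    Concave bands mirror them with the lower edge inclusive:
    S_6: mc < -0.8, S_7: -0.8 <= mc < -0.6, ..., S_11: -0.25 <= mc < -t.
    The flat band S_f = {|mc| <= t} (default t = 0.17) wins at its edges.
    """
    mc = np.asarray(field.mean, dtype=float)
    if not np.all(np.isfinite(mc)):
        bad = int(np.flatnonzero(~np.isfinite(mc))[0])
        raise CurvatureDataError(f"non-finite mean curvature at vertex {bad}")
    labels = np.full(len(mc), -1, dtype=int)  # -1 = flat
    flat = np.abs(mc) <= threshold_flat

    edges = list(_CONVEX_EDGES) + [threshold_flat]
    # convex: S_0 .. S_5
    labels[(mc > edges[0]) & ~flat] = 0
    for n in range(1, 6):
        labels[(mc > edges[n]) & (mc <= edges[n - 1]) & ~flat] = n
    # concave: S_6 .. S_11 (mirror image)
    labels[(mc < -edges[0]) & ~flat] = 6
    for n in range(1, 6):
        labels[(mc >= -edges[n - 1]) & (mc < -edges[n]) & ~flat] = 6 + n

    unassigned = (labels == -1) & ~flat
    if unassigned.any():  # can only happen with a threshold above 0.25
        flat = flat | unassigned
    subsets = {
        SUBSET_LABELS[n]: np.flatnonzero(labels == n) for n in range(12)
    }
    return SubsetPartition(
        flat=np.flatnonzero(flat), subsets=subsets, threshold_flat=threshold_flat
    )
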