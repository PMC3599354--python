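"""Seeded generator of six classes of synthetic lesion meshes.

Real lesion scans are not available, so the generator emulates the study
conditions: each specimen is a flat, evenly gridded patch (about 10
vertices per millimetre, nearly equilateral triangles) carrying one
centrally located surface lesion, modelled as a height-field deformation.
Six morphologically distinct classes are produced:

* ``abrasion`` — an irregular blob of band-limited random roughness
  (grazes have rounded indented/protruding features, no straight edges);
* ``incised`` — a narrow straight V-groove, much longer than deep
  (sharp-force cuts have straight wound edges);
* ``gunshot`` — a deep circular Gaussian-walled pit with a raised rim
  (round penetrating entry defect);
* ``smooth_strangulation`` — a flat-bottomed transverse furrow with steep
  smooth walls running across the whole patch (ligature indentation, e.g.
  a cable pressed into the surface);
* ``textured_strangulation`` — the same furrow whose floor carries
  periodic stria ridges (a woven lace leaves a striated furrow);
* ``patterned`` — an L-shaped sharp-walled indentation (the imprint of an
  edged instrument with delineated straight boundaries).

Within-class variability comes from seeded jitter of position, rotation,
depth and width, a gentle random base-surface undulation (a hand-flattened
block is never perfectly plane), and a per-instance patch extent drawn
around the nominal side length — the analogue of clipping a varying amount
of flat surround before the unit-square resize, which shifts every
normalized quantity of that instance coherently.  Height fields cannot
fold over, so every deformed patch remains a valid single-valued surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .mesh import TriangleMesh


class InjuryClass(str, Enum):
    ABRASION = "abrasion"
    INCISED = "incised"
    GUNSHOT = "gunshot"
    SMOOTH_STRANGULATION = "smooth_strangulation"
    TEXTURED_STRANGULATION = "textured_strangulation"
    PATTERNED = "patterned"


@dataclass
class InjuryClassSpec:
    """Deformation parameters of one class; lengths in millimetres."""

    class_id: InjuryClass
    depth: float = 1.0  # peak indentation depth
    width: float = 1.0  # characteristic feature width (half-width or radius)
    length: float = 5.0  # groove length (where applicable)
    roughness_amplitude: float = 0.0  # abrasion roughness sd
    roughness_corr: float = 0.6  # roughness correlation length
    stria_amplitude: float = 0.0  # ridge height along a textured furrow floor
    stria_period: float = 0.8  # ridge spacing
    arm_lengths: tuple[float, float] = (4.5, 3.5)  # patterned L arms
    wall_sharpness: float = 0.2  # tanh wall width of box-profile imprints
    rim_height: float = 0.0  # raised rim around a gunshot pit
    # gentle base-surface undulation present on every specimen; sd in mm
    # and correlation length in mm
    background_amplitude: float = 0.12
    background_corr: float = 2.0
    # within-class jitter (all seeded): multiplicative for depth/width,
    # absolute mm for position, degrees for rotation
    depth_jitter: float = 0.15
    width_jitter: float = 0.10
    position_jitter: float = 0.45
    rotation_jitter: float = 180.0


DEFAULT_CLASS_SPECS: dict[InjuryClass, InjuryClassSpec] = {
    InjuryClass.ABRASION: InjuryClassSpec(
        InjuryClass.ABRASION,
        depth=0.15,
        width=2.6,  # blob radius
        roughness_amplitude=0.10,
        roughness_corr=0.6,
        position_jitter=0.6,
    ),
    InjuryClass.INCISED: InjuryClassSpec(
        InjuryClass.INCISED, depth=1.0, width=0.3, length=5.5
    ),
    InjuryClass.GUNSHOT: InjuryClassSpec(
        InjuryClass.GUNSHOT, depth=1.8, width=1.2, rim_height=0.3
    ),
    InjuryClass.SMOOTH_STRANGULATION: InjuryClassSpec(
        InjuryClass.SMOOTH_STRANGULATION,
        depth=0.6,
        width=2.6,
        wall_sharpness=0.35,
        rotation_jitter=15.0,
        position_jitter=1.1,
    ),
    InjuryClass.TEXTURED_STRANGULATION: InjuryClassSpec(
        InjuryClass.TEXTURED_STRANGULATION,
        depth=0.6,
        width=2.6,
        wall_sharpness=0.35,
        stria_amplitude=0.10,
        stria_period=0.8,
        rotation_jitter=15.0,
        position_jitter=1.1,
    ),
    InjuryClass.PATTERNED: InjuryClassSpec(
        InjuryClass.PATTERNED,
        depth=0.8,
        width=1.2,  # arm width
        arm_lengths=(4.5, 3.5),
        wall_sharpness=0.2,
    ),
}


@dataclass
class GeneratorConfig:
    """Study-condition defaults: 6 x 18 patches of ~8 mm at ~10 vertices/mm."""

    resolution: int = 80  # vertices per side
    side_mm: float = 8.0
    side_jitter: float = 0.17  # fractional per-instance patch-extent jitter
    instances_per_class: int = 18
    master_seed: int = 0
    sensor_noise: float = 0.0  # i.i.d. vertex z-perturbation sd, mm
    class_specs: dict[InjuryClass, InjuryClassSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECS)
    )

    def __post_init__(self) -> None:
        if self.resolution < 20:
            raise ValueError("resolution must be >= 20")
        if self.instances_per_class < 2:
            raise ValueError("instances_per_class must be >= 2")
        if not (0.0 <= self.side_jitter < 1.0):
            raise ValueError("side_jitter must be in [0, 1)")


def base_grid_mesh(config: GeneratorConfig | None = None) -> TriangleMesh:
    """Flat n x n height-field grid with alternating diagonal splits.

    Vertices are row-major over (x, y); alternating the diagonal per cell
    keeps the triangle aspect near-equilateral on average and avoids a
    global diagonal bias in the curvature estimates.
    """
    config = config or GeneratorConfig()
    n = config.resolution
    coords = np.linspace(0.0, config.side_mm, n)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            v00 = r * n + c
            v10 = v00 + 1
            v01 = v00 + n
            v11 = v01 + 1
            if (r + c) % 2 == 0:
                faces.append((v00, v10, v11))
                faces.append((v00, v11, v01))
            else:
                faces.append((v00, v10, v01))
                faces.append((v10, v11, v01))
    return TriangleMesh(vertices, np.array(faces, dtype=np.int64), frame_tag="raw")


def _grid_shape(mesh: TriangleMesh) -> int:
    n = int(round(np.sqrt(mesh.n_vertices)))
    if n * n != mesh.n_vertices:
        raise ValueError("deform expects a square base grid mesh")
    return n


def deform(mesh: TriangleMesh, spec: InjuryClassSpec, seed: int) -> TriangleMesh:
    """Apply the class-characteristic height-field displacement.

    The input must be the flat base grid; the output shares its (x, y)
    lattice, so the deformed patch is still a fold-free height field.
    """
    rng = np.random.default_rng(seed)
    n = _grid_shape(mesh)
    V = mesh.vertices.copy()
    x, y = V[:, 0], V[:, 1]
    cx, cy = x.mean(), y.mean()
    side = x.max() - x.min()
    spacing = side / (n - 1)

    depth = spec.depth * (1.0 + spec.depth_jitter * rng.uniform(-1, 1))
    width = spec.width * (1.0 + spec.width_jitter * rng.uniform(-1, 1))
    ox = cx + spec.position_jitter * rng.uniform(-1, 1)
    oy = cy + spec.position_jitter * rng.uniform(-1, 1)
    theta = np.deg2rad(rng.uniform(-spec.rotation_jitter, spec.rotation_jitter))
    # lesion-aligned coordinates: u along the feature, v across it
    u = (x - ox) * np.cos(theta) + (y - oy) * np.sin(theta)
    v = -(x - ox) * np.sin(theta) + (y - oy) * np.cos(theta)

    cid = InjuryClass(spec.class_id)
    dz = np.zeros_like(x)
    if cid is InjuryClass.ABRASION:
        # band-limited roughness confined to an irregular central blob
        noise = rng.normal(size=(n, n))
        smooth = ndimage.gaussian_filter(noise, sigma=spec.roughness_corr / spacing)
        smooth = smooth / max(smooth.std(), 1e-12) * spec.roughness_amplitude
        r = np.hypot(u, v)
        # blob boundary wobbles with angle so the outline is irregular
        ang = np.arctan2(v, u)
        wobble = 1.0 + 0.25 * np.sin(3 * ang + rng.uniform(0, 2 * np.pi)) + 0.15 * np.sin(
            5 * ang + rng.uniform(0, 2 * np.pi)
        )
        mask = 0.5 * (1.0 - np.tanh((r - width * wobble) / 0.4))
        dz = (smooth.ravel() - depth) * mask
    elif cid is InjuryClass.INCISED:
        half_len = 0.5 * spec.length * (1.0 + 0.1 * rng.uniform(-1, 1))
        profile = np.maximum(0.0, 1.0 - np.abs(v) / width)  # V cross-section
        taper = 0.5 * (1.0 - np.tanh((np.abs(u) - half_len) / 0.3))
        dz = -depth * profile * taper
    elif cid is InjuryClass.GUNSHOT:
        r = np.hypot(u, v)
        pit = -depth * np.exp(-((r / width) ** 2))
        rim = spec.rim_height * np.exp(-(((r - 1.4 * width) / (0.5 * width)) ** 2))
        dz = pit + rim
    elif cid in (InjuryClass.SMOOTH_STRANGULATION, InjuryClass.TEXTURED_STRANGULATION):
        # flat-bottomed furrow with steep smooth (tanh) walls, full length;
        # the two wall lines give the class its long parallel curvature
        # ridges, quite unlike a V-groove or a circular pit
        s = spec.wall_sharpness
        box = 0.5 * (np.tanh((v + width / 2) / s) - np.tanh((v - width / 2) / s))
        dz = -depth * box
        if spec.stria_amplitude > 0:
            dz = dz + spec.stria_amplitude * np.cos(
                2 * np.pi * u / spec.stria_period
            ) * box
    elif cid is InjuryClass.PATTERNED:
        la, lb = spec.arm_lengths
        s = spec.wall_sharpness

        def box(a, b, la_):
            ina = 0.5 * (np.tanh((a + la_ / 2) / s) - np.tanh((a - la_ / 2) / s))
            inb = 0.5 * (np.tanh((b + width / 2) / s) - np.tanh((b - width / 2) / s))
            return ina * inb

        # two rectangular arms meeting at the origin in an L
        arm1 = box(u + la / 2 - width / 2, v, la)
        arm2 = box(v + lb / 2 - width / 2, u, lb)
        dz = -depth * np.clip(arm1 + arm2, 0.0, 1.0)
    else:  # pragma: no cover - InjuryClass() above already validates
        raise ValueError(f"unknown injury class {spec.class_id!r}")

    if spec.background_amplitude > 0:
        bg = ndimage.gaussian_filter(
            rng.normal(size=(n, n)), sigma=spec.background_corr / spacing
        )
        bg = bg / max(bg.std(), 1e-12) * spec.background_amplitude
        dz = dz + bg.ravel()

    V[:, 2] += dz
    return TriangleMesh(V, mesh.faces.copy(), frame_tag="raw")


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[list[TriangleMesh], pd.DataFrame]:
    """All instances of all six classes plus a labels table.

    Child seeds are derived deterministically from the master seed, so two
    runs with the same configuration produce bit-identical meshes.  Each
    instance gets its own patch extent (``side_jitter``) before the lesion
    is stamped in.
    """
    config = config or GeneratorConfig()
    n_total = 6 * config.instances_per_class
    child_seeds = (
        np.random.SeedSequence(config.master_seed).generate_state(2 * n_total + 1)
        % (2**31)
    )
    noise_rng = np.random.default_rng(int(child_seeds[-1]))
    meshes: list[TriangleMesh] = []
    records = []
    i = 0
    for cid in InjuryClass:
        spec = config.class_specs[cid]
        for inst in range(config.instances_per_class):
            extent_rng = np.random.default_rng(int(child_seeds[2 * i]))
            side = config.side_mm * (
                1.0 + config.side_jitter * extent_rng.uniform(-1, 1)
            )
            base = base_grid_mesh(
                GeneratorConfig(
                    resolution=config.resolution,
                    side_mm=side,
                    side_jitter=0.0,
                    instances_per_class=config.instances_per_class,
                    master_seed=config.master_seed,
                )
            )
            m = deform(base, spec, int(child_seeds[2 * i + 1]))
            if config.sensor_noise > 0:
                m.vertices[:, 2] += noise_rng.normal(
                    scale=config.sensor_noise, size=m.n_vertices
                )
            mesh_id = f"{cid.value}_{inst:02d}"
            meshes.append(m)
            records.append({"mesh_id": mesh_id, "class": cid.value})
            i += 1
    return meshes, pd.DataFrame.from_records(records)
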