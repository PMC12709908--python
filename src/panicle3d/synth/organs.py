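"""Procedural sorghum organ geometry: panicle, stem, leaf, whole plant.

Panicles are whorled branch tubes around a tapering rachis; stems are
chained internode cylinders whose top radius matches the peduncle; leaves
are drooping blade ribbons grafted at internode junctions.  All geometry is
metres, z-up, organ-local origin at the organ base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ..geometry import LEAF, PANICLE, STEM
from .meshutil import ribbon_mesh, tube_mesh
from .templates import LeafSpec, PanicleTemplate, StemSpec

__all__ = ["Organ", "Plant", "build_panicle", "build_stem", "build_leaf", "assemble_plant"]

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class Organ:
    """One labelled plant surface."""

    semantic: int
    mesh: trimesh.Trimesh

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.triangles


@dataclass
class Plant:
    """A single assembled plant: labelled organ surfaces plus metadata."""

    organs: list[Organ]
    template: PanicleTemplate
    stem_spec: StemSpec
    height: float  # stem height (panicle base z), metres
    _triangles: np.ndarray | None = field(default=None, repr=False)

    def all_triangles(self) -> np.ndarray:
        """Concatenated (T, 3, 3) triangle array over every organ (cached)."""
        if self._triangles is None:
            self._triangles = np.concatenate([o.triangles for o in self.organs])
        return self._triangles

    def bounds(self) -> np.ndarray:
        tri = self.all_triangles().reshape(-1, 3)
        return np.stack([tri.min(axis=0), tri.max(axis=0)])

    def transformed(self, yaw: float, translation: np.ndarray) -> "Plant":
        """Rigidly move the plant: rotate about its own z axis, then translate."""
        c, s = math.cos(yaw), math.sin(yaw)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = np.asarray(translation, dtype=float).reshape(3)
        organs = [
            Organ(o.semantic, trimesh.Trimesh(o.mesh.vertices @ rot.T + t,
                                              o.mesh.faces, process=False))
            for o in self.organs
        ]
        return Plant(organs, self.template, self.stem_spec, self.height)


def _branch_profile(t: np.ndarray, peak: float) -> np.ndarray:
    """Branch-reach envelope along the rachis: 0 at base, 1 at ``peak``."""
    x = np.clip(t / peak, 1e-6, None)
    return (x * np.exp(1.0 - x)) ** 0.7


def build_panicle(template: PanicleTemplate, rng: np.random.Generator) -> trimesh.Trimesh:
    """Build one panicle surface from a morphology template.

    The rachis is a gently bowed tapering tube; primary branches leave it in
    whorls, tilted up from horizontal by the template's branch elevation,
    with horizontal reach following a base-peaked envelope so the widest
    whorl spans ``max_width``.  Axis-aligned extents land within 10% of the
    template's length and width.
    """
    L, W = template.length, template.max_width
    if L <= 0 or W <= 0:
        raise ValueError("template length/width must be positive")
    bow_dir = rng.uniform(0, 2 * math.pi)
    bow_amp = 0.02 * L * rng.uniform(0.3, 1.0)
    zs = np.linspace(0.0, 0.96 * L, 8)
    bow = bow_amp * (zs / zs[-1]) ** 2
    rachis_path = np.column_stack(
        [bow * math.cos(bow_dir), bow * math.sin(bow_dir), zs]
    )
    rachis_radii = np.linspace(template.peduncle_radius, 0.35 * template.peduncle_radius, 8)
    meshes = [tube_mesh(rachis_path, rachis_radii, sections=5)]

    t_whorl = np.linspace(0.06, 0.92, template.n_whorls)
    az0 = rng.uniform(0, 2 * math.pi)
    tan_elev = math.tan(template.branch_elevation)
    for wi, t in enumerate(t_whorl):
        z0 = t * 0.96 * L
        reach = max(0.5 * W * _branch_profile(np.array([t]), template.branch_peak)[0], 0.006)
        for bi in range(template.branches_per_whorl):
            az = az0 + wi * _GOLDEN + bi * 2 * math.pi / template.branches_per_whorl
            az += rng.normal(0.0, 0.12)
            r_reach = reach * rng.uniform(0.9, 1.0)
            rise = min(r_reach * tan_elev, max(0.985 * L - z0, 0.004))
            d = np.array([math.cos(az), math.sin(az), 0.0])
            base = rachis_path[min(int(t * 7.99), 7)].copy()
            tip = base + d * r_reach + np.array([0, 0, rise])
            mid = 0.5 * (base + tip) + np.array([0, 0, 0.12 * rise + 0.002])
            path = np.stack([base, mid, tip])
            meshes.append(tube_mesh(path, np.array([0.0024, 0.0018, 0.0012]), sections=3))
    out = trimesh.util.concatenate(meshes)
    return trimesh.Trimesh(out.vertices, out.faces, process=False)


def build_stem(
    panicle_base_point: np.ndarray, peduncle_radius: float, spec: StemSpec
) -> trimesh.Trimesh:
    """Build the stem as chained internode cylinders up to the panicle base.

    The internode lengths of ``spec`` are rescaled so the chain spans from
    the ground plane to the panicle base; curvature appears as a lateral
    offset growing quadratically with height (the tip offset equals
    ``curvature * height``); the top radius equals the peduncle radius.
    """
    base_pt = np.asarray(panicle_base_point, dtype=float).reshape(3)
    h = float(base_pt[2])
    if h <= 0:
        raise ValueError(f"panicle base must sit above the ground plane, got z={h}")
    if peduncle_radius <= 0:
        raise ValueError("peduncle_radius must be > 0")
    lengths = np.asarray(spec.internode_lengths, dtype=float)
    heights = np.concatenate([[0.0], np.cumsum(lengths)]) / lengths.sum() * h
    # subdivide for smooth curvature
    zs = np.unique(np.concatenate([heights, np.linspace(0, h, 2 * len(lengths) + 1)]))
    frac = zs / h
    offset = spec.curvature * h * frac**2
    path = np.column_stack(
        [base_pt[0] - spec.curvature * h + offset, np.full_like(zs, base_pt[1]), zs]
    )
    radii = spec.base_radius + (peduncle_radius - spec.base_radius) * frac
    return tube_mesh(path, radii, sections=8)


def stem_junction_points(
    panicle_base_point: np.ndarray, spec: StemSpec
) -> np.ndarray:
    """Internode junction coordinates on the (curved) stem axis, base to top."""
    base_pt = np.asarray(panicle_base_point, dtype=float).reshape(3)
    h = float(base_pt[2])
    lengths = np.asarray(spec.internode_lengths, dtype=float)
    zj = np.cumsum(lengths)[:-1] / lengths.sum() * h
    frac = zj / h
    offset = spec.curvature * h * frac**2
    return np.column_stack(
        [base_pt[0] - spec.curvature * h + offset, np.full_like(zj, base_pt[1]), zj]
    )


def build_leaf(
    spec: LeafSpec, graft_point: np.ndarray, azimuth: float
) -> trimesh.Trimesh:
    """Build a leaf blade: a drooping ribbon leaving ``graft_point``.

    The midrib rises at ~34 degrees and bends downward by
    ``midrib_curvature`` radians over its arc; total arc length equals the
    blade length exactly.  The blade widens to ``max_blade_width`` near its
    middle and narrows to a tip.
    """
    if spec.blade_length <= 0 or spec.max_blade_width <= 0:
        raise ValueError("leaf blade length/width must be positive")
    graft = np.asarray(graft_point, dtype=float).reshape(3)
    nseg = 14
    s = np.linspace(0.0, 1.0, nseg + 1)
    phi = 0.6 - spec.midrib_curvature * s**1.3
    ds = spec.blade_length / nseg
    d_xy = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    steps = ds * (np.cos(phi)[:, None] * d_xy + np.sin(phi)[:, None] * [0, 0, 1.0])
    midrib = graft + np.concatenate([[np.zeros(3)], np.cumsum(steps[:-1], axis=0)])
    t = s
    half_w = 0.5 * spec.max_blade_width * np.clip(np.sin(math.pi * (0.06 + 0.9 * t)), 0.05, None)
    across = np.tile(np.array([-math.sin(azimuth), math.cos(azimuth), 0.0]), (nseg + 1, 1))
    return ribbon_mesh(midrib, half_w, across)


def assemble_plant(
    template: PanicleTemplate,
    stem_spec: StemSpec,
    leaf_specs: list[LeafSpec],
    rng: np.random.Generator,
) -> Plant:
    """Assemble one plant: panicle atop the stem, leaves at internode junctions.

    Leaf azimuths alternate across the row direction (about +-90 degrees
    from +x with jitter), emulating the distichous phyllotaxy of sorghum; a
    plant with no leaves is valid and stands for a defoliated/emerging stage.
    """
    h = stem_spec.height
    base_pt = np.array([0.0, 0.0, h])
    stem_mesh = build_stem(base_pt, template.peduncle_radius, stem_spec)
    panicle_mesh = build_panicle(template, rng)
    panicle_mesh = trimesh.Trimesh(
        panicle_mesh.vertices + base_pt, panicle_mesh.faces, process=False
    )
    organs = [Organ(PANICLE, panicle_mesh), Organ(STEM, stem_mesh)]
    junctions = stem_junction_points(base_pt, stem_spec)
    for i, leaf in enumerate(leaf_specs):
        j = min(leaf.attachment_index, len(junctions) - 1) if len(junctions) else None
        if j is None:
            break
        side = 1.0 if i % 2 == 0 else -1.0
        azimuth = side * math.pi / 2.0 + rng.normal(0.0, 0.35)
        organs.append(Organ(LEAF, build_leaf(leaf, junctions[j], azimuth)))
    return Plant(organs, template, stem_spec, height=h)
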