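"""Low-level mesh helpers for the procedural canopy generator.

Tubes (stems, rachis, branches), ribbons (leaf blades), deterministic
area-weighted surface sampling, and a segment-triangle mesh intersection
test used to reject overlapping plant placements.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = [
    "tube_mesh",
    "ribbon_mesh",
    "sample_surface",
    "meshes_intersect",
]


def _frames_along(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex orthonormal frame (u, v) perpendicular to a polyline."""
    path = np.asarray(path, dtype=float)
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True) + 1e-12
    ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(tangents, ref)
    bad = np.linalg.norm(u, axis=1) < 1e-6
    u[bad] = np.cross(tangents[bad], [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u, axis=1, keepdims=True) + 1e-12
    v = np.cross(tangents, u)
    v /= np.linalg.norm(v, axis=1, keepdims=True) + 1e-12
    return u, v


def tube_mesh(path: np.ndarray, radii: np.ndarray | float, sections: int = 6) -> trimesh.Trimesh:
    """Open-ended tube swept along a polyline with per-vertex radii."""
    path = np.asarray(path, dtype=float).reshape(-1, 3)
    n = path.shape[0]
    if n < 2:
        raise ValueError("tube path needs at least 2 points")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    if np.any(radii <= 0):
        raise ValueError("tube radii must be positive")
    u, v = _frames_along(path)
    ang = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring = np.cos(ang)[:, None, None] * u[None] + np.sin(ang)[:, None, None] * v[None]
    verts = (path[None] + ring * radii[None, :, None]).transpose(1, 0, 2).reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for j in range(sections):
            a = i * sections + j
            b = i * sections + (j + 1) % sections
            c = (i + 1) * sections + j
            d = (i + 1) * sections + (j + 1) % sections
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def ribbon_mesh(
    midrib: np.ndarray, half_widths: np.ndarray, across: np.ndarray
) -> trimesh.Trimesh:
    """Flat blade: a strip around a midrib, widened along unit vectors ``across``."""
    midrib = np.asarray(midrib, dtype=float).reshape(-1, 3)
    n = midrib.shape[0]
    half_widths = np.broadcast_to(np.asarray(half_widths, dtype=float), (n,))
    across = np.asarray(across, dtype=float).reshape(-1, 3)
    left = midrib - across * half_widths[:, None]
    right = midrib + across * half_widths[:, None]
    verts = np.empty((2 * n, 3))
    verts[0::2] = left
    verts[1::2] = right
    faces = []
    for i in range(n - 1):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        faces.append([a, b, d])
        faces.append([a, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def sample_surface(
    triangles: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` points area-proportionally from a (T, 3, 3) triangle array.

    Returns the points and the index of the triangle each point came from.
    """
    tri = np.asarray(triangles, dtype=float)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    total = areas.sum()
    if total <= 0:
        raise ValueError("degenerate surface: zero total area")
    tri_idx = rng.choice(tri.shape[0], size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a, b, c = tri[tri_idx, 0], tri[tri_idx, 1], tri[tri_idx, 2]
    pts = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c
    return pts, tri_idx


# ---------------------------------------------------------------------------
# mesh-mesh intersection (segment-triangle crossings, AABB prefiltered)


def _segments_hit_triangles(
    p0: np.ndarray, p1: np.ndarray, tri: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """Moller-Trumbore: does segment i cross triangle i?  All arrays paired."""
    d = p1 - p0
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps  # parallel segments (incl. coplanar) never hit
    inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = p0 - tri[:, 0]
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    return ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t >= 0) & (t <= 1)


def _tri_pairs_intersect(tri_a: np.ndarray, tri_b: np.ndarray) -> np.ndarray:
    """Pairwise triangle intersection via the 6 edge-vs-triangle crossings."""
    hits = np.zeros(tri_a.shape[0], dtype=bool)
    for i, j in ((0, 1), (1, 2), (2, 0)):
        hits |= _segments_hit_triangles(tri_a[:, i], tri_a[:, j], tri_b)
        hits |= _segments_hit_triangles(tri_b[:, i], tri_b[:, j], tri_a)
    return hits


def meshes_intersect(tri_a: np.ndarray, tri_b: np.ndarray) -> bool:
    """True if any triangle of surface A crosses any triangle of surface B.

    Candidate pairs are pruned by per-triangle AABB overlap before the exact
    edge-crossing tests; coplanar-contact pairs count as non-intersecting.
    """
    tri_a = np.asarray(tri_a, dtype=float)
    tri_b = np.asarray(tri_b, dtype=float)
    if tri_a.size == 0 or tri_b.size == 0:
        return False
    lo_a, hi_a = tri_a.min(axis=1), tri_a.max(axis=1)
    lo_b, hi_b = tri_b.min(axis=1), tri_b.max(axis=1)
    if np.any(lo_a.min(0) > hi_b.max(0)) or np.any(lo_b.min(0) > hi_a.max(0)):
        return False
    overlap = (
        (lo_a[:, None, :] <= hi_b[None, :, :]) & (lo_b[None, :, :] <= hi_a[:, None, :])
    ).all(axis=2)
    ia, ib = np.nonzero(overlap)
    if ia.size == 0:
        return False
    # chunk to bound peak memory on dense overlaps
    for s in range(0, ia.size, 200_000):
        sl = slice(s, s + 200_000)
        if _tri_pairs_intersect(tri_a[ia[sl]], tri_b[ib[sl]]).any():
            return True
    return False
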