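"""Deterministic geometric kernels shared by the generator, model and evaluator.

Farthest-point sampling, sphere/cylinder neighbourhood queries, inverse-
distance feature interpolation, rotated-box IoU, NMS, the proposal occupancy
filter, and oriented-box fitting.  All operators are pure functions of their
inputs; any tie is broken by lowest index so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "OrientedBox",
    "NeighborhoodGroups",
    "farthest_point_sample",
    "radius_query",
    "inverse_distance_interpolate",
    "box_iou_3d",
    "nms_3d",
    "occupancy_filter",
    "fit_instance_box",
]

PANICLE, STEM, LEAF = 0, 1, 2  # semantic class codes used throughout


def wrap_angle(a: float) -> float:
    """Wrap an angle to [-pi, pi)."""
    return float((a + math.pi) % (2.0 * math.pi) - math.pi)


@dataclass
class OrientedBox:
    """A 3D box with extents and a yaw rotation about the vertical axis.

    ``yaw`` is measured from the +x axis (the row direction) in radians and
    stored wrapped to [-pi, pi).  ``dims`` are full extents along the box's
    local x/y/z axes, metres.
    """

    center: np.ndarray
    dims: np.ndarray
    yaw: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.dims = np.asarray(self.dims, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.center)) or not np.all(np.isfinite(self.dims)):
            raise ValueError("box center/dims must be finite")
        if np.any(self.dims <= 0):
            raise ValueError(f"box dims must be positive, got {self.dims}")
        self.yaw = wrap_angle(float(self.yaw))

    @property
    def volume(self) -> float:
        return float(np.prod(self.dims))

    def bev_polygon(self, xy_scale: float = 1.0) -> Polygon:
        """Footprint rectangle in the xy plane, optionally shrunk in x and y."""
        hx, hy = self.dims[0] * xy_scale / 2.0, self.dims[1] * xy_scale / 2.0
        c, s = math.cos(self.yaw), math.sin(self.yaw)
        corners = np.array([[-hx, -hy], [hx, -hy], [hx, hy], [-hx, hy]])
        rot = np.array([[c, -s], [s, c]])
        return Polygon(corners @ rot.T + self.center[:2])

    def z_interval(self) -> tuple[float, float]:
        hz = self.dims[2] / 2.0
        return self.center[2] - hz, self.center[2] + hz

    def contains(
        self, points: np.ndarray, xy_scale: float = 1.0, eps: float = 1e-9
    ) -> np.ndarray:
        """Boolean mask of points inside the box (x/y extents scaled by
        ``xy_scale``); ``eps`` absorbs round-off for boundary points."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        d = pts - self.center
        c, s = math.cos(-self.yaw), math.sin(-self.yaw)
        lx = c * d[:, 0] - s * d[:, 1]
        ly = s * d[:, 0] + c * d[:, 1]
        hx = self.dims[0] * xy_scale / 2.0 + eps
        hy = self.dims[1] * xy_scale / 2.0 + eps
        hz = self.dims[2] / 2.0 + eps
        return (
            (np.abs(lx) <= hx) & (np.abs(ly) <= hy) & (np.abs(d[:, 2]) <= hz)
        )

    def corners(self) -> np.ndarray:
        """8x3 array of box corner coordinates."""
        hx, hy, hz = self.dims / 2.0
        sign = np.array(
            [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)],
            dtype=float,
        )
        local = sign * [hx, hy, hz]
        c, s = math.cos(self.yaw), math.sin(self.yaw)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return local @ rot.T + self.center

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "dims": [float(v) for v in self.dims],
            "yaw": float(self.yaw),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrientedBox":
        return cls(np.array(d["center"]), np.array(d["dims"]), float(d["yaw"]))


# ---------------------------------------------------------------------------
# farthest-point sampling

try:  # numba speeds the O(k*N) loop up ~30x; the numpy path is identical
    from numba import njit

    @njit(cache=False)
    def _fps_loop(pts: np.ndarray, k: int, start: int) -> np.ndarray:
        n = pts.shape[0]
        chosen = np.empty(k, dtype=np.int64)
        mind = np.full(n, np.inf)
        cur = start
        for i in range(k):
            chosen[i] = cur
            px, py, pz = pts[cur, 0], pts[cur, 1], pts[cur, 2]
            best = -1.0
            nxt = 0
            for j in range(n):
                dx = pts[j, 0] - px
                dy = pts[j, 1] - py
                dz = pts[j, 2] - pz
                d = dx * dx + dy * dy + dz * dz
                if d < mind[j]:
                    mind[j] = d
                if mind[j] > best:
                    best = mind[j]
                    nxt = j
            cur = nxt
        return chosen

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _fps_numpy(pts: np.ndarray, k: int, start: int) -> np.ndarray:
    n = pts.shape[0]
    chosen = np.empty(k, dtype=np.int64)
    mind = np.full(n, np.inf)
    cur = start
    for i in range(k):
        chosen[i] = cur
        d = np.einsum("ij,ij->i", pts - pts[cur], pts - pts[cur])
        np.minimum(mind, d, out=mind)
        cur = int(np.argmax(mind))  # first max -> lowest-index tie-break
    return chosen


def farthest_point_sample(
    points: np.ndarray, k: int, start_index: int = 0
) -> np.ndarray:
    """Greedy farthest-point subsampling of a point set.

    Starting from ``start_index``, each successive pick maximises the minimum
    distance to all previously chosen points; ties go to the lowest index.
    Returns ``k`` unique indices into ``points``.  The output is prefix-
    stable: the first ``j`` indices of a ``k``-sample equal the ``j``-sample.
    """
    pts = np.ascontiguousarray(np.asarray(points, dtype=np.float64).reshape(-1, 3))
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if not 0 <= start_index < n:
        raise ValueError(f"start_index out of range: {start_index}")
    if _HAVE_NUMBA:
        return np.asarray(_fps_loop(pts, int(k), int(start_index)))
    return _fps_numpy(pts, int(k), int(start_index))


# ---------------------------------------------------------------------------
# neighbourhood queries


@dataclass
class NeighborhoodGroups:
    """Fixed-width neighbourhood index groups around query centers.

    ``indices`` is (n_centers, max_samples) into the source point set; groups
    with fewer than ``max_samples`` true neighbours are padded by repeating
    their first member (the set-abstraction convention), with the true count
    kept in ``counts``.  A center with no neighbour at all is padded with its
    nearest source point and has count 0.  ``mode`` records the query
    geometry: ``"sphere"`` is a 3D ball, ``"cylinder"`` an xy-disc of the
    same radius extended over the full z range.
    """

    indices: np.ndarray
    counts: np.ndarray
    radius: float
    mode: str
    empty_source: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("sphere", "cylinder"):
            raise ValueError(f"mode must be 'sphere' or 'cylinder', got {self.mode!r}")


def radius_query(
    centers: np.ndarray,
    points: np.ndarray,
    radius: float,
    max_samples: int,
    mode: str = "sphere",
) -> NeighborhoodGroups:
    """Group source points around centers within a sphere or vertical cylinder.

    Sphere mode keeps points within Euclidean 3D distance <= radius of a
    center; cylinder mode keeps points whose xy-plane distance is <= radius
    regardless of their z, which matches the elongated vertical footprint of
    a panicle-plus-stem column.  When more than ``max_samples`` neighbours
    exist the ``max_samples`` nearest (by the mode's own distance) are kept.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if max_samples < 1:
        raise ValueError(f"max_samples must be >= 1, got {max_samples}")
    if mode not in ("sphere", "cylinder"):
        raise ValueError(f"mode must be 'sphere' or 'cylinder', got {mode!r}")
    ctr = np.asarray(centers, dtype=float).reshape(-1, 3)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    m = ctr.shape[0]
    if pts.shape[0] == 0:
        return NeighborhoodGroups(
            indices=np.zeros((m, max_samples), dtype=np.int64),
            counts=np.zeros(m, dtype=np.int64),
            radius=float(radius),
            mode=mode,
            empty_source=True,
        )
    if mode == "sphere":
        q_pts, q_ctr = pts, ctr
    else:
        q_pts, q_ctr = pts[:, :2], ctr[:, :2]
    tree = cKDTree(q_pts)
    neighbor_lists = tree.query_ball_point(q_ctr, r=float(radius))
    indices = np.zeros((m, max_samples), dtype=np.int64)
    counts = np.zeros(m, dtype=np.int64)
    for i, nbrs in enumerate(neighbor_lists):
        if len(nbrs) == 0:
            _, nearest = tree.query(q_ctr[i])
            indices[i, :] = nearest
            continue
        nbrs = np.sort(np.asarray(nbrs, dtype=np.int64))
        if len(nbrs) > max_samples:
            d = np.linalg.norm(q_pts[nbrs] - q_ctr[i], axis=1)
            order = np.argsort(d, kind="stable")[:max_samples]
            nbrs = nbrs[np.sort(order)]
        counts[i] = len(nbrs)
        indices[i, : len(nbrs)] = nbrs
        indices[i, len(nbrs):] = nbrs[0]
    return NeighborhoodGroups(
        indices=indices, counts=counts, radius=float(radius), mode=mode
    )


def inverse_distance_interpolate(
    targets: np.ndarray,
    sources: np.ndarray,
    source_features: np.ndarray,
    k: int = 3,
    delta: float = 1e-8,
) -> np.ndarray:
    """Interpolate features onto target points from their k nearest sources.

    Each target receives ``sum(w_i f_i) / sum(w_i)`` over its ``k`` nearest
    sources with weights ``w_i = 1 / (d_i + delta)``; ``delta`` regularises
    a target coinciding with a source, which then dominates the average.
    ``k`` is clamped to the number of sources.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tgt = np.asarray(targets, dtype=float).reshape(-1, 3)
    src = np.asarray(sources, dtype=float).reshape(-1, 3)
    if src.shape[0] == 0:
        raise ValueError("sources must be non-empty")
    feats = np.asarray(source_features, dtype=float)
    feats2d = feats.reshape(src.shape[0], -1)
    k = min(k, src.shape[0])
    tree = cKDTree(src)
    dist, idx = tree.query(tgt, k=k)
    dist = np.atleast_2d(dist.reshape(tgt.shape[0], k))
    idx = idx.reshape(tgt.shape[0], k)
    w = 1.0 / (dist + delta)
    out = np.einsum("tk,tkf->tf", w, feats2d[idx]) / w.sum(axis=1, keepdims=True)
    if feats.ndim == 1:
        return out[:, 0]
    return out


# ---------------------------------------------------------------------------
# rotated-box IoU, NMS, occupancy filter


def box_iou_3d(a: OrientedBox, b: OrientedBox) -> float:
    """Exact IoU of two yaw-rotated boxes.

    Intersection volume decomposes into the polygon overlap of the two
    bird's-eye-view footprints times the overlap of the z intervals (both
    boxes are upright, so the decomposition is exact).
    """
    az0, az1 = a.z_interval()
    bz0, bz1 = b.z_interval()
    dz = min(az1, bz1) - max(az0, bz0)
    if dz <= 0:
        return 0.0
    inter_area = a.bev_polygon().intersection(b.bev_polygon()).area
    inter = inter_area * dz
    union = a.volume + b.volume - inter
    if union <= 0:
        return 0.0
    return float(min(1.0, inter / union))


def nms_3d(
    boxes: list[OrientedBox], scores: np.ndarray, iou_threshold: float
) -> list[int]:
    """Greedy non-maximum suppression on oriented boxes.

    Boxes are visited in descending score order (lowest index first on score
    ties); a box is suppressed if its IoU with an already-kept box exceeds
    ``iou_threshold``.  Returns kept indices in visit order.
    """
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if len(boxes) != scores.shape[0]:
        raise ValueError(
            f"|boxes| = {len(boxes)} does not match |scores| = {scores.shape[0]}"
        )
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for i in order:
        i = int(i)
        if all(box_iou_3d(boxes[i], boxes[j]) <= iou_threshold for j in kept):
            kept.append(i)
    return kept


def occupancy_filter(
    boxes: list[OrientedBox],
    points: np.ndarray,
    semantic_labels: np.ndarray,
    crop_volume_fraction: float = 0.2,
    panicle_label: int = PANICLE,
) -> np.ndarray:
    """Keep proposals whose central core contains at least one panicle point.

    Each box is centre-cropped in the xy plane: x and y extents are scaled by
    ``sqrt(crop_volume_fraction)`` (z untouched) so the cropped volume equals
    ``crop_volume_fraction`` times the box volume.  A box survives iff at
    least one point labelled panicle falls inside that core — proposals
    hovering over empty space or pure leaf/stem regions are dropped.
    """
    if not 0 < crop_volume_fraction <= 1:
        raise ValueError(
            f"crop_volume_fraction must lie in (0, 1], got {crop_volume_fraction}"
        )
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    labels = np.asarray(semantic_labels).reshape(-1)
    panicle_pts = pts[labels == panicle_label]
    xy_scale = math.sqrt(crop_volume_fraction)
    keep = np.zeros(len(boxes), dtype=bool)
    if panicle_pts.shape[0] == 0:
        return keep
    for i, box in enumerate(boxes):
        keep[i] = bool(box.contains(panicle_pts, xy_scale=xy_scale).any())
    return keep


def fit_instance_box(instance_points: np.ndarray) -> OrientedBox:
    """Fit a yaw-oriented box to the points of one panicle instance.

    The z extent is the min/max of z; the xy footprint is the minimal-area
    rotated rectangle of the xy projection (rotating calipers via shapely),
    with yaw normalised to [-pi/2, pi/2).  Degenerate inputs — fewer than 3
    points, or xy-collinear points — are rejected.
    """
    pts = np.asarray(instance_points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise ValueError(f"need >= 3 points to fit a box, got {pts.shape[0]}")
    hull = MultiPoint(pts[:, :2]).convex_hull
    rect = hull.minimum_rotated_rectangle
    if rect.geom_type != "Polygon" or rect.area <= 1e-12:
        raise ValueError("xy projection is degenerate (collinear points)")
    xy = np.asarray(rect.exterior.coords)[:4]
    e0 = xy[1] - xy[0]
    e1 = xy[2] - xy[1]
    len0, len1 = np.linalg.norm(e0), np.linalg.norm(e1)
    # local x axis along edge e0; normalise yaw into [-pi/2, pi/2)
    yaw = math.atan2(e0[1], e0[0])
    dx, dy = float(len0), float(len1)
    if yaw >= math.pi / 2 or yaw < -math.pi / 2:
        yaw = wrap_angle(yaw + math.pi)
    z0, z1 = float(pts[:, 2].min()), float(pts[:, 2].max())
    dz = max(z1 - z0, 1e-6)
    center = np.array(
        [rect.centroid.x, rect.centroid.y, (z0 + z1) / 2.0], dtype=float
    )
    return OrientedBox(center=center, dims=np.array([dx, dy, dz]), yaw=yaw)
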