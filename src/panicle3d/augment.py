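"""Training-time point-cloud augmentation with class-aware noise.

All transforms preserve semantic and instance labels exactly.  Rotation is
restricted to the xy plane (gravity direction is meaningful), rescaling is
bounded to keep panicles within their size classes, and jitter is
class-aware: leaf points move more than panicle and stem points, and a
displaced non-panicle point is never allowed to merge into a panicle
neighbourhood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import LEAF, PANICLE, STEM, wrap_angle
from .synth.cloud import AnnotatedCloud

__all__ = [
    "AugmentConfig",
    "rotate_about_z",
    "random_dropout",
    "classwise_jitter",
    "rescale",
    "compose",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters.

    ``jitter_sigma`` maps class code -> Gaussian displacement sigma in
    metres; the leaf sigma exceeds panicle/stem so canopy structure blurs
    while heads stay crisp.  ``merge_epsilon`` is the minimum distance a
    displaced non-panicle point must keep from every panicle point.
    ``dropout_range`` and ``scale_range`` are sampled uniformly per cloud.
    """

    rotation: bool = True
    dropout_range: tuple[float, float] = (0.2, 0.5)
    jitter_sigma: dict[int, float] = field(
        default_factory=lambda: {PANICLE: 0.002, STEM: 0.002, LEAF: 0.010}
    )
    merge_epsilon: float = 0.005
    scale_range: tuple[float, float] = (0.85, 1.15)
    shuffle: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.dropout_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError(f"invalid dropout range {self.dropout_range}")
        if any(s < 0 for s in self.jitter_sigma.values()):
            raise ValueError("jitter sigmas must be >= 0")
        if self.scale_range[0] <= 0:
            raise ValueError("scale range must be positive")


def rotate_about_z(cloud: AnnotatedCloud, angle: float) -> AnnotatedCloud:
    """Rotate the scene about the vertical axis through its xy centroid.

    z coordinates are untouched; box centers co-rotate and box yaws advance
    by ``angle`` (re-wrapped), so annotations stay consistent.
    """
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")
    out = cloud.copy()
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    pivot = out.coords[:, :2].mean(axis=0) if out.n_points else np.zeros(2)
    out.coords[:, :2] = (out.coords[:, :2] - pivot) @ rot.T + pivot
    for box in out.boxes:
        box.center[:2] = rot @ (box.center[:2] - pivot) + pivot
        box.yaw = wrap_angle(box.yaw + angle)
    return out


def random_dropout(
    cloud: AnnotatedCloud, p: float, rng: np.random.Generator
) -> AnnotatedCloud:
    """Remove each point independently with probability ``p``; boxes unchanged."""
    if not 0 <= p <= 1:
        raise ValueError(f"dropout probability must lie in [0, 1], got {p}")
    survivors = rng.random(cloud.n_points) >= p
    return cloud.select(survivors)


def classwise_jitter(
    cloud: AnnotatedCloud,
    config: AugmentConfig,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> AnnotatedCloud:
    """Gaussian per-point displacement with class-specific sigmas.

    A displaced stem/leaf point that lands within ``merge_epsilon`` of a
    panicle point is re-drawn up to ``max_retries`` times and otherwise
    restored to its original position, so noise never bleeds non-panicle
    points into panicle neighbourhoods (points that already start inside
    the epsilon shell are left untouched).  Labels never change.
    """
    out = cloud.copy()
    if out.n_points == 0:
        return out
    sigmas = np.array(
        [config.jitter_sigma.get(c, 0.0) for c in range(3)], dtype=float
    )
    sigma_per_point = sigmas[out.semantic]
    displaced = out.coords + rng.normal(size=(out.n_points, 3)) * sigma_per_point[:, None]
    pan_mask = out.semantic == PANICLE
    pan_pts = cloud.coords[pan_mask]
    if pan_pts.shape[0] and config.merge_epsilon > 0:
        tree = cKDTree(pan_pts)
        check = ~pan_mask & (sigma_per_point > 0)
        idx = np.nonzero(check)[0]
        # points starting inside the shell are exempt (e.g. stem tops at the
        # peduncle junction); the constraint is about noise-induced merging
        d_orig, _ = tree.query(cloud.coords[idx])
        exempt = d_orig < config.merge_epsilon
        displaced[idx[exempt]] = cloud.coords[idx[exempt]]
        active = idx[~exempt]
        for _ in range(max_retries):
            if active.size == 0:
                break
            d, _ = tree.query(displaced[active])
            bad = d < config.merge_epsilon
            if not bad.any():
                break
            redraw = active[bad]
            displaced[redraw] = cloud.coords[redraw] + rng.normal(
                size=(redraw.size, 3)
            ) * sigma_per_point[redraw, None]
            active = redraw
        if active.size:
            d, _ = tree.query(displaced[active])
            still_bad = active[d < config.merge_epsilon]
            displaced[still_bad] = cloud.coords[still_bad]
    out.coords = displaced
    return out


def rescale(
    cloud: AnnotatedCloud, factor: float, config: AugmentConfig | None = None
) -> AnnotatedCloud:
    """Uniformly rescale the scene about its centroid.

    Coordinates, box centers and box dims scale together; size-class labels
    are retained unchanged (the training scale range is bounded precisely so
    classes stay valid).  A factor outside the configured range is legal but
    logged when a config is supplied.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    if config is not None and not (
        config.scale_range[0] <= factor <= config.scale_range[1]
    ):
        log.warning(
            "scale factor %.3f outside configured range %s", factor, config.scale_range
        )
    out = cloud.copy()
    pivot = out.coords.mean(axis=0) if out.n_points else np.zeros(3)
    out.coords = (out.coords - pivot) * factor + pivot
    for box in out.boxes:
        box.center = (box.center - pivot) * factor + pivot
        box.dims = box.dims * factor
    return out


def compose(
    cloud: AnnotatedCloud, config: AugmentConfig, rng: np.random.Generator
) -> AnnotatedCloud:
    """Apply the full augmentation chain in fixed order.

    rotate -> rescale -> jitter -> dropout -> shuffle, with the rotation
    angle, scale factor and dropout probability drawn from ``config``.  The
    output is a pure function of (cloud, config, rng state).
    """
    out = cloud
    if config.rotation:
        out = rotate_about_z(out, float(rng.uniform(-math.pi, math.pi)))
    out = rescale(out, float(rng.uniform(*config.scale_range)), config)
    out = classwise_jitter(out, config, rng)
    out = random_dropout(out, float(rng.uniform(*config.dropout_range)), rng)
    if config.shuffle:
        out = out.select(rng.permutation(out.n_points))
    return out
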