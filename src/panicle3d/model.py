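"""SegVoteNet: multi-task semantic segmentation + 3D panicle detection.

A shared set-abstraction (SA) encoder feeds two branches: a feature-
propagation (FP) decoder that labels every point as panicle/stem/leaf, and
a detection branch whose seeds are farthest-point-sampled from the points
the segmentation branch calls panicle.  Seed features are aggregated with
cylinder queries (full-height vertical receptive fields), each seed casts
two votes toward a panicle center, votes are aggregated into oriented box
proposals, and proposals are decoded as a size class + residual and a
heading bin + residual.

The estimator follows the scikit-learn protocol: construct with
hyper-parameters, ``fit`` on a list of annotated clouds, ``predict`` on a
raw coordinate array; fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import (
    PANICLE,
    OrientedBox,
    farthest_point_sample,
    nms_3d,
    occupancy_filter,
    radius_query,
    wrap_angle,
)
from .nn import MLP, AdamW, Linear, Tensor, concat, gather_rows
from .synth.cloud import AnnotatedCloud
from .synth.templates import size_class_table

__all__ = [
    "SALayerConfig",
    "EncoderConfig",
    "SegHeadConfig",
    "DetectHeadConfig",
    "TrainConfig",
    "SegVoteNet",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class SALayerConfig:
    """One set-abstraction layer: sample count, query geometry and PointNets."""

    n_sample: int
    radii: tuple[float, ...]
    group_sizes: tuple[int, ...]
    mlps: tuple[tuple[int, ...], ...]
    mode: str = "sphere"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("query radii must be positive")
        if not len(self.radii) == len(self.group_sizes) == len(self.mlps):
            raise ValueError("radii, group_sizes and mlps must align")


@dataclass(frozen=True)
class EncoderConfig:
    """The four-SA-layer shared encoder.

    The default mirrors the published architecture: multi-scale grouping in
    the first two layers, single-scale in the last two, with sample counts
    2560/1024/512/256 and ball radii chosen at panicle scale (metres).
    """

    layers: tuple[SALayerConfig, ...] = (
        SALayerConfig(2560, (0.05, 0.1), (128, 64), ((16, 16, 32), (16, 16, 32))),
        SALayerConfig(1024, (0.1, 0.2), (64, 32), ((32, 32, 64), (64, 64, 128))),
        SALayerConfig(512, (0.4,), (32,), ((128, 128, 256),)),
        SALayerConfig(256, (0.8,), (32,), ((128, 128, 256),)),
    )

    def __post_init__(self) -> None:
        counts = [l.n_sample for l in self.layers]
        if any(a <= b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"sample counts must strictly decrease, got {counts}")

    @property
    def out_dims(self) -> list[int]:
        return [sum(m[-1] for m in l.mlps) for l in self.layers]


@dataclass(frozen=True)
class SegHeadConfig:
    """Segmentation decoder: four FP layers plus a per-point classifier.

    Class weights counteract the canopy imbalance (leaves dominate, stems
    are sparse): panicle 0.3, stem 0.6, leaf 0.1.
    """

    fp_widths: tuple[int, ...] = (256, 256)
    classifier_widths: tuple[int, ...] = (256, 256, 3)
    class_weights: tuple[float, float, float] = (0.3, 0.6, 0.1)

    def __post_init__(self) -> None:
        if self.classifier_widths[-1] != 3:
            raise ValueError("classifier must emit 3 class logits")


@dataclass(frozen=True)
class DetectHeadConfig:
    """Detection branch: panicle-seeded voting with cylinder grouping.

    ``seed_radius``/``agg_radius`` are the cylinder base radii (0.075 m and
    0.1 m) whose vertical extent spans the whole canopy; each seed casts
    ``votes_per_seed`` = 2 votes.  ``mean_size`` holds the per-size-class
    mean box dims the size residuals are measured against; it must match
    the generator's size-class export.  ``use_panicle_seeds`` and
    ``cylinder_grouping`` exist as ablation switches.
    """

    n_seeds: int = 1024
    seed_radius: float = 0.075
    seed_group_size: int = 32
    seed_mlp: tuple[int, ...] = (256, 256)
    vote_mlp: tuple[int, ...] = (256, 256)
    votes_per_seed: int = 2
    n_proposals: int = 256
    agg_radius: float = 0.1
    agg_group_size: int = 16
    agg_mlp: tuple[int, ...] = (256, 128, 128)
    head_mlp: tuple[int, ...] = (128, 128)
    n_size_classes: int = 4
    mean_size: tuple[tuple[float, float, float], ...] = tuple(
        tuple(float(v) for v in row) for row in size_class_table()[1]
    )
    n_heading_bins: int = 12
    near_threshold: float = 0.15
    far_threshold: float = 0.3
    use_panicle_seeds: bool = True
    cylinder_grouping: bool = True

    def __post_init__(self) -> None:
        if self.votes_per_seed != 2:
            raise ValueError("the voting module casts exactly 2 votes per seed")
        if self.seed_radius <= 0 or self.agg_radius <= 0:
            raise ValueError("cylinder radii must be positive")
        if len(self.mean_size) != self.n_size_classes:
            raise ValueError("mean_size must have one row per size class")

    @property
    def grouping_mode(self) -> str:
        return "cylinder" if self.cylinder_grouping else "sphere"


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: AdamW at 0.002, decayed 10x at epochs 24 and 32."""

    lr: float = 0.002
    lr_decay: float = 0.1
    decay_epochs: tuple[int, ...] = (24, 32)
    batch_size: int = 8
    n_epochs: int = 36
    val_interval: int = 10
    input_points: int | None = 20_000
    weight_decay: float = 0.01
    loss_weights: dict = field(
        default_factory=lambda: {
            "segmentation": 1.0,
            "vote": 1.0,
            "objectness": 0.5,
            "center": 1.0,
            "size_class": 0.1,
            "size_residual": 1.0,
            "heading_class": 0.1,
            "heading_residual": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if list(self.decay_epochs) != sorted(self.decay_epochs):
            raise ValueError("decay epochs must increase")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        n = sum(epoch >= e for e in self.decay_epochs)
        return self.lr * self.lr_decay**n


def _scale_widths(widths: tuple[int, ...], s: float, floor: int = 8) -> tuple[int, ...]:
    return tuple(max(int(round(w * s)), floor) for w in widths)


def small_profile(
    width_scale: float = 0.25,
    samples: tuple[int, int, int, int] = (512, 256, 128, 64),
    n_seeds: int = 128,
    n_proposals: int = 32,
) -> tuple[EncoderConfig, SegHeadConfig, DetectHeadConfig]:
    """Reduced-width configs for desk-scale experiments and tests."""
    base = EncoderConfig()
    layers = tuple(
        SALayerConfig(
            n_sample=samples[i],
            radii=l.radii,
            group_sizes=tuple(max(g // 2, 8) for g in l.group_sizes),
            mlps=tuple(_scale_widths(m, width_scale) for m in l.mlps),
            mode=l.mode,
        )
        for i, l in enumerate(base.layers)
    )
    seg = SegHeadConfig(
        fp_widths=_scale_widths((256, 256), width_scale),
        classifier_widths=_scale_widths((256, 256), width_scale) + (3,),
    )
    det = DetectHeadConfig(
        n_seeds=n_seeds,
        seed_group_size=16,
        seed_mlp=_scale_widths((256, 256), width_scale),
        vote_mlp=_scale_widths((256, 256), width_scale),
        n_proposals=n_proposals,
        agg_group_size=8,
        agg_mlp=_scale_widths((256, 128, 128), width_scale),
        head_mlp=_scale_widths((128, 128), width_scale),
    )
    return EncoderConfig(layers=layers), seg, det


# ---------------------------------------------------------------------------
# forward-pass record


@dataclass
class Forward:
    """Everything one forward pass produces (arrays are numpy, activations
    are autograd Tensors)."""

    coords: np.ndarray
    sa_xyz: list[np.ndarray]
    sa_feats: list[Tensor]
    seg_logits: Tensor
    pred_labels: np.ndarray
    seed_indices: np.ndarray
    seed_xyz: np.ndarray
    seed_fallback: bool
    votes: Tensor  # (n_seeds, 2, 3)
    vote_feats: Tensor  # (n_seeds, 2, C)
    proposal_centers: Tensor  # (P, 3)
    objectness: Tensor  # (P, 2)
    size_logits: Tensor  # (P, n_size_classes)
    size_residuals: Tensor  # (P, n_size_classes, 3)
    heading_logits: Tensor  # (P, n_heading_bins)
    heading_residuals: Tensor  # (P, n_heading_bins)


def _canonical_start(points: np.ndarray) -> int:
    """FPS start rule: the lexicographically smallest coordinate, so the
    sampling is invariant to input point order."""
    return int(np.lexsort((points[:, 2], points[:, 1], points[:, 0]))[0])


class SegVoteNet(BaseEstimator):
    """Multi-task panicle segmentation + detection estimator.

    Parameters
    ----------
    encoder, seg_head, detect_head : config dataclasses or None
        ``None`` selects the full published architecture for
        ``profile="paper"`` or reduced widths for ``profile="small"``.
    train : TrainConfig or None
        Optimization schedule; ``None`` uses the defaults.
    augment : AugmentConfig or None
        When set, each training scene is re-augmented every epoch.
    seed : int
        Master seed for initialisation, input subsampling and augmentation.

    Attributes
    ----------
    params_ : list of Parameter, the trained weights.
    history_ : dict with per-step ``loss`` records and periodic ``val`` records.
    n_steps_ : number of optimizer steps taken.
    """

    def __init__(
        self,
        encoder: EncoderConfig | None = None,
        seg_head: SegHeadConfig | None = None,
        detect_head: DetectHeadConfig | None = None,
        train: TrainConfig | None = None,
        augment=None,
        profile: str = "paper",
        seed: int = 0,
    ):
        self.encoder = encoder
        self.seg_head = seg_head
        self.detect_head = detect_head
        self.train = train
        self.augment = augment
        self.profile = profile
        self.seed = seed

    # -- config resolution --------------------------------------------------
    def _configs(self) -> tuple[EncoderConfig, SegHeadConfig, DetectHeadConfig, TrainConfig]:
        if self.profile not in ("paper", "small"):
            raise ValueError(f"unknown profile {self.profile!r}")
        enc, seg, det = (
            (EncoderConfig(), SegHeadConfig(), DetectHeadConfig())
            if self.profile == "paper"
            else small_profile()
        )
        return (
            self.encoder or enc,
            self.seg_head or seg,
            self.detect_head or det,
            self.train or TrainConfig(),
        )

    # -- parameter construction ----------------------------------------------
    def _build(self) -> None:
        enc, seg, det, _ = self._configs()
        rng = np.random.default_rng(self.seed)
        self.encoder_, self.seg_head_, self.detect_head_ = enc, seg, det
        mods: dict[str, object] = {}
        in_dim = 0
        for li, layer in enumerate(enc.layers):
            for si, mlp in enumerate(layer.mlps):
                mods[f"sa{li}_{si}"] = MLP(3 + in_dim, list(mlp), rng)
            in_dim = enc.out_dims[li]
        dims = [0] + enc.out_dims  # feature dims at levels 0..4
        prev = dims[4]
        for li in (3, 2, 1, 0):
            mods[f"fp{li}"] = MLP(dims[li] + prev, list(seg.fp_widths), rng)
            prev = seg.fp_widths[-1]
        mods["classifier"] = MLP(prev, list(seg.classifier_widths), rng, final_relu=False)
        seed_in = 3 + prev + 3  # rel-xyz + FP features + one-hot labels
        mods["seed_sa"] = MLP(seed_in, list(det.seed_mlp), rng)
        vote_dim = det.seed_mlp[-1]
        mods["vote_mlp"] = MLP(vote_dim, list(det.vote_mlp), rng)
        mods["vote_out"] = Linear(det.vote_mlp[-1], det.votes_per_seed * (3 + vote_dim), rng)
        mods["agg"] = MLP(3 + vote_dim, list(det.agg_mlp), rng)
        mods["head"] = MLP(det.agg_mlp[-1], list(det.head_mlp), rng)
        head_out = 2 + 3 + det.n_size_classes * 4 + det.n_heading_bins * 2
        mods["head_out"] = Linear(det.head_mlp[-1], head_out, rng)
        self.modules_ = mods
        self.params_ = [
            p
            for m in mods.values()
            for p in m.parameters()
        ]
        self.history_ = {"loss": [], "val": []}
        self.n_steps_ = 0

    def _ensure_built(self) -> None:
        if not hasattr(self, "modules_"):
            self._build()

    # -- architecture pieces --------------------------------------------------
    def encode(self, coords: np.ndarray) -> tuple[list[np.ndarray], list[Tensor | None]]:
        """Run the shared SA encoder.

        Returns per-level point arrays and feature tensors for levels
        0 (input, no features) through 4.  Inputs smaller than a layer's
        sample count clamp that layer's output size.
        """
        self._ensure_built()
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if coords.shape[0] == 0:
            raise ValueError("cannot encode an empty cloud")
        xyz_levels: list[np.ndarray] = [coords]
        feat_levels: list[Tensor | None] = [None]
        xyz, feats = coords, None
        for li, layer in enumerate(self.encoder_.layers):
            n_s = min(layer.n_sample, xyz.shape[0])
            if n_s < layer.n_sample:
                log.debug("SA%d: clamping sample count %d -> %d", li, layer.n_sample, n_s)
            idx = farthest_point_sample(xyz, n_s, _canonical_start(xyz))
            new_xyz = xyz[idx]
            scales = []
            for si, (r, k) in enumerate(zip(layer.radii, layer.group_sizes)):
                groups = radius_query(new_xyz, xyz, r, k, layer.mode)
                rel = Tensor(xyz[groups.indices] - new_xyz[:, None, :])
                x = (
                    concat([rel, gather_rows(feats, groups.indices)], axis=-1)
                    if feats is not None
                    else rel
                )
                scales.append(self.modules_[f"sa{li}_{si}"](x).max(axis=1))
            feats = scales[0] if len(scales) == 1 else concat(scales, axis=-1)
            xyz = new_xyz
            xyz_levels.append(xyz)
            feat_levels.append(feats)
        return xyz_levels, feat_levels

    def _interpolate(
        self, targets: np.ndarray, sources: np.ndarray, feats: Tensor, k: int = 3
    ) -> Tensor:
        from scipy.spatial import cKDTree

        k = min(k, sources.shape[0])
        dist, idx = cKDTree(sources).query(targets, k=k)
        dist = dist.reshape(targets.shape[0], k)
        idx = idx.reshape(targets.shape[0], k)
        w = 1.0 / (dist + 1e-8)
        w = w / w.sum(axis=1, keepdims=True)
        out = None
        for j in range(k):
            term = gather_rows(feats, idx[:, j]) * Tensor(w[:, j : j + 1])
            out = term if out is None else out + term
        return out

    def segment(
        self, xyz_levels: list[np.ndarray], feat_levels: list[Tensor | None]
    ) -> tuple[Tensor, Tensor]:
        """FP decoder + classifier: per-point features and class logits."""
        feats = feat_levels[4]
        for li in (3, 2, 1, 0):
            interp = self._interpolate(xyz_levels[li], xyz_levels[li + 1], feats)
            if feat_levels[li] is not None:
                interp = concat([feat_levels[li], interp], axis=-1)
            feats = self.modules_[f"fp{li}"](interp)
        logits = self.modules_["classifier"](feats)
        return feats, logits

    def sample_seeds(
        self,
        fp_points: np.ndarray,
        predicted_labels: np.ndarray,
        n_seeds: int,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, bool]:
        """FPS seed selection restricted to panicle-predicted points.

        Falls back to FPS over all points (flagged) when the segmentation
        branch predicts no panicle at all; samples with replacement when
        fewer than ``n_seeds`` panicle points exist.
        """
        if fp_points.shape[0] == 0:
            raise ValueError("cannot sample seeds from an empty point set")
        use_seg = self.detect_head_.use_panicle_seeds
        pan_idx = np.nonzero(predicted_labels == PANICLE)[0] if use_seg else np.arange(
            fp_points.shape[0]
        )
        fallback = pan_idx.size == 0
        if fallback:
            pan_idx = np.arange(fp_points.shape[0])
        if pan_idx.size >= n_seeds:
            sub = farthest_point_sample(
                fp_points[pan_idx], n_seeds, _canonical_start(fp_points[pan_idx])
            )
            chosen = pan_idx[sub]
        else:
            extra = rng.choice(pan_idx, size=n_seeds - pan_idx.size, replace=True)
            chosen = np.concatenate([pan_idx, extra])
        return chosen, fallback

    def panicle_vote(
        self,
        seed_indices: np.ndarray,
        fp_points: np.ndarray,
        fp_feats: Tensor,
        pred_labels: np.ndarray,
    ) -> tuple[Tensor, Tensor]:
        """The Panicle Vote Module: cylinder-grouped seed features -> 2 votes.

        Each seed aggregates the final FP layer's features (with one-hot
        predicted labels appended) over a 0.075 m cylinder query, passes
        them through the seed PointNet and the voting MLP, and emits two
        votes: a center offset added to the seed position plus a vote
        feature (seed feature + learned offset).
        """
        det = self.detect_head_
        onehot = np.eye(3)[np.clip(pred_labels, 0, 2)]
        feats_aug = concat([fp_feats, Tensor(onehot)], axis=-1)
        seed_xyz = fp_points[seed_indices]
        groups = radius_query(
            seed_xyz, fp_points, det.seed_radius, det.seed_group_size, det.grouping_mode
        )
        rel = Tensor(fp_points[groups.indices] - seed_xyz[:, None, :])
        x = concat([rel, gather_rows(feats_aug, groups.indices)], axis=-1)
        seed_feat = self.modules_["seed_sa"](x).max(axis=1)  # (S, C)
        h = self.modules_["vote_mlp"](seed_feat)
        out = self.modules_["vote_out"](h)  # (S, 2*(3+C))
        s = seed_xyz.shape[0]
        c = self.detect_head_.seed_mlp[-1]
        out = out.reshape(s, det.votes_per_seed, 3 + c)
        offsets = out[:, :, :3]
        feat_off = out[:, :, 3:]
        votes = Tensor(seed_xyz[:, None, :]) + offsets
        vote_feats = seed_feat.reshape(s, 1, c) + feat_off
        return votes, vote_feats

    def aggregate_and_predict(
        self, votes: Tensor, vote_feats: Tensor
    ) -> dict[str, Tensor]:
        """Vote aggregation + proposal heads.

        FPS-selects proposal centers among votes, groups votes within a
        0.1 m cylinder, pools them with the aggregation PointNet, and emits
        objectness, refined center, size class + residuals and heading bin
        + residuals per proposal.
        """
        det = self.detect_head_
        v = votes.reshape(-1, 3)
        vf = vote_feats.reshape(v.shape[0], -1)
        v_np = v.data
        n_prop = min(det.n_proposals, v_np.shape[0])
        sel = farthest_point_sample(v_np, n_prop, _canonical_start(v_np))
        centers = gather_rows(v, sel)
        groups = radius_query(
            v_np[sel], v_np, det.agg_radius, det.agg_group_size, det.grouping_mode
        )
        rel = gather_rows(v, groups.indices) - centers.reshape(n_prop, 1, 3)
        x = concat([rel, gather_rows(vf, groups.indices)], axis=-1)
        agg = self.modules_["agg"](x).max(axis=1)
        h = self.modules_["head"](agg)
        out = self.modules_["head_out"](h)
        ns, nh = det.n_size_classes, det.n_heading_bins
        i = 0
        objectness = out[:, i : i + 2]; i += 2
        center_off = out[:, i : i + 3]; i += 3
        size_logits = out[:, i : i + ns]; i += ns
        size_res = out[:, i : i + ns * 3].reshape(n_prop, ns, 3); i += ns * 3
        head_logits = out[:, i : i + nh]; i += nh
        head_res = out[:, i : i + nh]
        return {
            "centers": centers + center_off,
            "objectness": objectness,
            "size_logits": size_logits,
            "size_residuals": size_res,
            "heading_logits": head_logits,
            "heading_residuals": head_res,
        }

    def forward(
        self, coords: np.ndarray, rng: np.random.Generator | None = None
    ) -> Forward:
        """Full forward pass on one cloud."""
        rng = rng or np.random.default_rng(self.seed)
        xyz_levels, feat_levels = self.encode(coords)
        fp_feats, logits = self.segment(xyz_levels, feat_levels)
        pred = np.argmax(logits.data, axis=1)
        n_seeds = min(self.detect_head_.n_seeds, xyz_levels[0].shape[0])
        seed_idx, fallback = self.sample_seeds(xyz_levels[0], pred, n_seeds, rng)
        votes, vote_feats = self.panicle_vote(seed_idx, xyz_levels[0], fp_feats, pred)
        prop = self.aggregate_and_predict(votes, vote_feats)
        return Forward(
            coords=xyz_levels[0],
            sa_xyz=xyz_levels[1:],
            sa_feats=[f for f in feat_levels[1:]],
            seg_logits=logits,
            pred_labels=pred,
            seed_indices=seed_idx,
            seed_xyz=xyz_levels[0][seed_idx],
            seed_fallback=fallback,
            votes=votes,
            vote_feats=vote_feats,
            proposal_centers=prop["centers"],
            objectness=prop["objectness"],
            size_logits=prop["size_logits"],
            size_residuals=prop["size_residuals"],
            heading_logits=prop["heading_logits"],
            heading_residuals=prop["heading_residuals"],
        )

    # -- losses ----------------------------------------------------------------
    def _heading_bin(self, yaw: float) -> tuple[int, float]:
        nh = self.detect_head_.n_heading_bins
        width = 2 * np.pi / nh
        shifted = wrap_angle(yaw) + np.pi
        b = min(int(shifted // width), nh - 1)
        residual = shifted - (b + 0.5) * width
        return b, residual

    def _heading_decode(self, b: int, residual: float) -> float:
        width = 2 * np.pi / self.detect_head_.n_heading_bins
        return wrap_angle((b + 0.5) * width + residual - np.pi)

    def compute_losses(self, fw: Forward, cloud: AnnotatedCloud) -> dict[str, Tensor]:
        """All named loss terms plus their weighted total.

        Segmentation: class-weighted cross-entropy (0.3/0.6/0.1, normalised
        by point count so each class's contribution is linear in its
        weight).  Vote: L1 between each positive seed's best vote and its
        instance's box center.  Objectness: cross-entropy with near/far
        center-distance assignment (< 0.15 m positive, > 0.3 m negative).
        Center: smooth-L1 in both directions (proposals to matched GT
        centers, GT centers to nearest proposal).  Size/heading: class
        cross-entropy plus smooth-L1 on the true class's residual.
        """
        det, seg_cfg = self.detect_head_, self.seg_head_
        tcfg = self.train or TrainConfig()
        w = tcfg.loss_weights
        losses: dict[str, Tensor] = {}

        # segmentation
        labels = cloud.semantic
        ls = fw.seg_logits.log_softmax(axis=1)
        nll = -ls[np.arange(labels.shape[0]), labels]
        cw = np.asarray(seg_cfg.class_weights)[labels]
        losses["segmentation"] = (nll * Tensor(cw)).sum() * (1.0 / labels.shape[0])

        boxes = cloud.boxes
        gt_centers = np.stack([b.center for b in boxes]) if boxes else np.zeros((0, 3))

        # vote loss: seeds on ground-truth panicle instances pull toward centers
        inst_of_seed = cloud.instance[fw.seed_indices]
        box_by_inst = {int(i): b for i, b in zip(cloud.box_instance_ids, boxes)}
        pos_seed = np.array(
            [j for j, i in enumerate(inst_of_seed) if int(i) in box_by_inst], dtype=int
        )
        if pos_seed.size:
            targets = np.stack(
                [box_by_inst[int(inst_of_seed[j])].center for j in pos_seed]
            )
            diffs = gather_rows(fw.votes.reshape(-1, det.votes_per_seed, 3), pos_seed) - Tensor(
                targets[:, None, :]
            )
            per_vote = diffs.abs().sum(axis=2)  # (S+, 2)
            losses["vote"] = per_vote.min(axis=1).mean()
        else:
            losses["vote"] = Tensor(0.0)

        # objectness and box losses
        centers_np = fw.proposal_centers.data
        n_prop = centers_np.shape[0]
        if gt_centers.shape[0]:
            d = np.linalg.norm(centers_np[:, None, :] - gt_centers[None], axis=2)
            nearest = d.argmin(axis=1)
            dmin = d.min(axis=1)
            pos = dmin < det.near_threshold
            neg = dmin > det.far_threshold
        else:
            nearest = np.zeros(n_prop, dtype=int)
            pos = np.zeros(n_prop, dtype=bool)
            neg = np.ones(n_prop, dtype=bool)
        care = pos | neg
        obj_ls = fw.objectness.log_softmax(axis=1)
        target_cls = pos.astype(int)
        if care.any():
            losses["objectness"] = (-obj_ls[np.arange(n_prop), target_cls])[
                np.nonzero(care)[0]
            ].mean()
        else:
            losses["objectness"] = Tensor(0.0)

        pos_idx = np.nonzero(pos)[0]
        if pos_idx.size and gt_centers.shape[0]:
            matched = Tensor(gt_centers[nearest[pos_idx]])
            diff = gather_rows(fw.proposal_centers, pos_idx) - matched
            fwd = diff.smooth_l1(0.1).sum(axis=1).mean()
            # reverse direction: every GT center pulls its nearest proposal
            rev_sel = np.linalg.norm(
                centers_np[None] - gt_centers[:, None, :], axis=2
            ).argmin(axis=1)
            rdiff = gather_rows(fw.proposal_centers, rev_sel) - Tensor(gt_centers)
            losses["center"] = fwd + rdiff.smooth_l1(0.1).sum(axis=1).mean()

            gt_cls = cloud.size_classes[nearest[pos_idx]]
            sl = fw.size_logits.log_softmax(axis=1)
            losses["size_class"] = (-sl[pos_idx, gt_cls]).mean()
            mean_size = np.asarray(det.mean_size)
            gt_dims = np.stack([boxes[j].dims for j in nearest[pos_idx]])
            res_target = gt_dims / mean_size[gt_cls] - 1.0
            pred_res = fw.size_residuals[pos_idx, gt_cls, :]
            losses["size_residual"] = (
                (pred_res - Tensor(res_target)).smooth_l1(0.15).sum(axis=1).mean()
            )

            gt_bins, gt_res = zip(
                *(self._heading_bin(boxes[j].yaw) for j in nearest[pos_idx])
            )
            gt_bins = np.asarray(gt_bins)
            hl = fw.heading_logits.log_softmax(axis=1)
            losses["heading_class"] = (-hl[pos_idx, gt_bins]).mean()
            pred_hres = fw.heading_residuals[pos_idx, gt_bins]
            losses["heading_residual"] = (
                (pred_hres - Tensor(np.asarray(gt_res))).smooth_l1(0.3).mean()
            )
        else:
            for k in ("center", "size_class", "size_residual", "heading_class",
                      "heading_residual"):
                losses[k] = Tensor(0.0)

        total = None
        for name, term in losses.items():
            weighted = term * w.get(name, 1.0)
            total = weighted if total is None else total + weighted
        losses["total"] = total
        return losses

    # -- decoding / inference ---------------------------------------------------
    def decode_proposals(self, fw: Forward) -> tuple[list[OrientedBox], np.ndarray]:
        """Proposal tensors -> oriented boxes + objectness scores."""
        det = self.detect_head_
        centers = fw.proposal_centers.data
        obj = fw.objectness.data
        scores = np.exp(obj[:, 1]) / (np.exp(obj[:, 0]) + np.exp(obj[:, 1]))
        size_cls = fw.size_logits.data.argmax(axis=1)
        mean_size = np.asarray(det.mean_size)
        boxes = []
        for i in range(centers.shape[0]):
            res = np.clip(fw.size_residuals.data[i, size_cls[i]], -0.9, 3.0)
            dims = mean_size[size_cls[i]] * (1.0 + res)
            hb = int(fw.heading_logits.data[i].argmax())
            yaw = self._heading_decode(hb, float(fw.heading_residuals.data[i, hb]))
            boxes.append(OrientedBox(centers[i], dims, yaw))
        return boxes, scores

    def infer(
        self,
        coords: np.ndarray,
        nms_iou: float = 0.25,
        crop_fraction: float = 0.2,
        score_threshold: float = 0.5,
    ) -> dict:
        """Detection + segmentation on one cloud.

        Proposals are decoded, filtered by the panicle-occupancy test on the
        central 20% of each box's xy footprint (using the segmentation
        branch's own labels), then greedily suppressed at ``nms_iou``.
        """
        self._ensure_built()
        fw = self.forward(np.asarray(coords, dtype=float))
        boxes, scores = self.decode_proposals(fw)
        keep = occupancy_filter(boxes, fw.coords, fw.pred_labels, crop_fraction)
        keep &= scores >= score_threshold
        idx = np.nonzero(keep)[0]
        boxes_k = [boxes[i] for i in idx]
        kept = nms_3d(boxes_k, scores[idx], nms_iou)
        final = [idx[j] for j in kept]
        return {
            "boxes": [boxes[i] for i in final],
            "scores": scores[final],
            "labels": fw.pred_labels,
            "seed_fallback": fw.seed_fallback,
        }

    # -- training ----------------------------------------------------------------
    def fit(self, X, y=None, validation=None):
        """Train on a list of :class:`AnnotatedCloud` scenes.

        The AdamW learning rate starts at ``train.lr`` and decays by
        ``train.lr_decay`` at each epoch in ``train.decay_epochs``; scenes
        are shuffled each epoch and grads averaged over ``batch_size``
        scenes per step.  When ``validation`` scenes are given, detection
        mAP at IoU 0.25/0.5 and segmentation accuracy are recorded every
        ``val_interval`` epochs.  Non-finite losses abort with a diagnostic.
        """
        scenes = list(X)
        if not scenes:
            raise ValueError("training set is empty")
        self._build()
        tcfg = self.train or TrainConfig()
        rng = np.random.default_rng(self.seed)
        opt = AdamW(self.params_, lr=tcfg.lr, weight_decay=tcfg.weight_decay)
        step = 0
        for epoch in range(tcfg.n_epochs):
            opt.lr = tcfg.lr_at(epoch)
            order = rng.permutation(len(scenes))
            for b0 in range(0, len(order), tcfg.batch_size):
                batch = order[b0 : b0 + tcfg.batch_size]
                opt.zero_grad()
                batch_loss = 0.0
                for si in batch:
                    cloud = scenes[si]
                    if self.augment is not None:
                        from .augment import compose

                        cloud = compose(cloud, self.augment, rng)
                    cloud = self._subsample(cloud, tcfg.input_points, rng)
                    fw = self.forward(cloud.coords, rng)
                    losses = self.compute_losses(fw, cloud)
                    total = losses["total"] * (1.0 / len(batch))
                    val = float(total.data)
                    if not np.isfinite(val):
                        parts = {k: float(v.data) for k, v in losses.items()}
                        raise RuntimeError(
                            f"training diverged at epoch {epoch} step {step}: {parts}"
                        )
                    total.backward()
                    batch_loss += val
                opt.step()
                self.history_["loss"].append(
                    {"step": step, "epoch": epoch, "loss": batch_loss, "lr": opt.lr}
                )
                step += 1
            if validation is not None and (epoch + 1) % tcfg.val_interval == 0:
                self.history_["val"].append(
                    {"epoch": epoch, **self.evaluate(validation)}
                )
        self.n_steps_ = step
        return self

    @staticmethod
    def _subsample(
        cloud: AnnotatedCloud, n: int | None, rng: np.random.Generator
    ) -> AnnotatedCloud:
        if n is None or cloud.n_points <= n:
            return cloud
        return cloud.select(rng.choice(cloud.n_points, size=n, replace=False))

    def evaluate(self, scenes, iou_thresholds=(0.25, 0.5)) -> dict:
        """Detection mAP/mAR and segmentation accuracy over scenes."""
        from .evaluate import average_precision, segmentation_accuracy

        out: dict = {}
        aps = {t: [] for t in iou_thresholds}
        ars = {t: [] for t in iou_thresholds}
        seg_accs = []
        for cloud in scenes:
            res = self.infer(cloud.coords)
            for t in iou_thresholds:
                ap, ar = average_precision(
                    res["boxes"], res["scores"], cloud.boxes, t
                )
                aps[t].append(ap)
                ars[t].append(ar)
            seg_accs.append(
                segmentation_accuracy(res["labels"], cloud.semantic, mode="all-class")
            )
        for t in iou_thresholds:
            out[f"mAP@{t}"] = float(np.mean(aps[t]))
            out[f"mAR@{t}"] = float(np.mean(ars[t]))
        out["segmentation_accuracy"] = float(np.mean(seg_accs))
        return out

    def predict(self, coords: np.ndarray) -> dict:
        """Alias for :meth:`infer` on raw coordinates (sklearn-style)."""
        return self.infer(coords)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: weights + configs in one .npz."""
        self._ensure_built()
        enc, seg, det, tcfg = self._configs()
        meta = {
            "profile": self.profile,
            "seed": self.seed,
            "encoder": [
                {
                    "n_sample": l.n_sample,
                    "radii": list(l.radii),
                    "group_sizes": list(l.group_sizes),
                    "mlps": [list(m) for m in l.mlps],
                    "mode": l.mode,
                }
                for l in enc.layers
            ],
            "seg_head": {
                "fp_widths": list(seg.fp_widths),
                "classifier_widths": list(seg.classifier_widths),
                "class_weights": list(seg.class_weights),
            },
            "detect_head": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in det.__dict__.items()
                if k != "mean_size"
            },
            "mean_size": [list(r) for r in det.mean_size],
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params_)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegVoteNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        enc = EncoderConfig(
            layers=tuple(
                SALayerConfig(
                    n_sample=l["n_sample"],
                    radii=tuple(l["radii"]),
                    group_sizes=tuple(l["group_sizes"]),
                    mlps=tuple(tuple(m) for m in l["mlps"]),
                    mode=l["mode"],
                )
                for l in meta["encoder"]
            )
        )
        seg = SegHeadConfig(
            fp_widths=tuple(meta["seg_head"]["fp_widths"]),
            classifier_widths=tuple(meta["seg_head"]["classifier_widths"]),
            class_weights=tuple(meta["seg_head"]["class_weights"]),
        )
        dh = dict(meta["detect_head"])
        for key in ("seed_mlp", "vote_mlp", "agg_mlp", "head_mlp"):
            dh[key] = tuple(dh[key])
        det = DetectHeadConfig(
            mean_size=tuple(tuple(r) for r in meta["mean_size"]), **dh
        )
        model = cls(
            encoder=enc, seg_head=seg, detect_head=det,
            profile=meta["profile"], seed=meta["seed"],
        )
        model._build()
        for i, p in enumerate(model.params_):
            p.data = data[f"p{i}"]
        return model
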