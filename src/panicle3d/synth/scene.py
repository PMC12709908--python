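"""Plot-scene assembly, surface sampling, and dataset finalization.

``place_plants`` lays plants along a row with drawn spacings and rejects
any candidate whose surfaces intersect an already-placed plant;
``sample_scene`` draws an area-weighted labelled point cloud from the
scene's surfaces; ``finalize_cloud`` crops to the upper canopy,
FPS-downsamples to the training cardinality, and attaches one oriented box
and size class per panicle instance; ``generate_dataset`` writes seeded
scene files plus a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..geometry import PANICLE, farthest_point_sample, fit_instance_box
from ..io import write_annotations, write_ply
from .cloud import AnnotatedCloud
from .meshutil import meshes_intersect, sample_surface
from .organs import Plant, assemble_plant
from .templates import (
    LeafSpec,
    PanicleTemplate,
    PlotSpec,
    StemSpec,
    assign_size_class_array,
    size_class_table,
)

__all__ = [
    "Scene",
    "place_plants",
    "sample_scene",
    "finalize_cloud",
    "assign_size_class",
    "generate_dataset",
]

log = logging.getLogger(__name__)

MIN_POINTS_PER_BOX = 50  # instances below this keep labels but get no box


@dataclass
class Scene:
    """Placed plants of one plot plus the layout bookkeeping."""

    plants: list[Plant]
    plot_spec: PlotSpec
    spacings: list[float] = field(default_factory=list)
    n_rejected_slots: int = 0

    def labelled_triangles(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All scene triangles with per-triangle semantic and instance labels."""
        tris, sems, insts = [], [], []
        for iid, plant in enumerate(self.plants):
            for organ in plant.organs:
                t = organ.triangles
                tris.append(t)
                sems.append(np.full(len(t), organ.semantic, dtype=int))
                insts.append(
                    np.full(len(t), iid if organ.semantic == PANICLE else -1, dtype=int)
                )
        if not tris:
            raise ValueError("scene contains no plants")
        return np.concatenate(tris), np.concatenate(sems), np.concatenate(insts)


def _draw_plant(spec: PlotSpec, rng: np.random.Generator) -> Plant:
    template = spec.template_pool[rng.integers(len(spec.template_pool))].jittered(rng)
    h = float(rng.uniform(*spec.stem_height_range))
    n_inter = int(rng.integers(4, 8))
    lengths = rng.uniform(0.7, 1.3, n_inter)
    lengths = tuple(lengths / lengths.sum() * h)
    stem = StemSpec(
        internode_lengths=lengths,
        base_radius=0.016,
        top_radius=template.peduncle_radius,
        curvature=float(rng.uniform(0.0, 0.04)),
    )
    n_leaves = int(rng.integers(spec.n_leaves_range[0], spec.n_leaves_range[1] + 1))
    leaves = [
        LeafSpec(
            blade_length=float(rng.uniform(0.35, 0.55)),
            max_blade_width=float(rng.uniform(0.05, 0.08)),
            midrib_curvature=float(rng.uniform(1.2, 1.7)),
            attachment_index=int(rng.integers(0, max(n_inter - 1, 1))),
        )
        for _ in range(n_leaves)
    ]
    return assemble_plant(template, stem, leaves, rng)


def _plants_overlap(a: Plant, b: Plant) -> bool:
    ba, bb = a.bounds(), b.bounds()
    if np.any(ba[0] > bb[1]) or np.any(bb[0] > ba[1]):
        return False
    return meshes_intersect(a.all_triangles(), b.all_triangles())


def place_plants(plot_spec: PlotSpec, rng: np.random.Generator) -> Scene:
    """Populate a plot grid with non-overlapping plants.

    Plants are placed sequentially along each row at spacings drawn from the
    spec's range; a candidate whose surfaces intersect any already-placed
    plant is redrawn (fresh template, stem, leaves, pose) up to the retry
    cap, after which the slot stays empty.  Gap injection leaves a
    contiguous span of the row unplanted, emulating failed establishment.
    """
    plants: list[Plant] = []
    spacings: list[float] = []
    rejected = 0
    for row in range(plot_spec.n_rows):
        y0 = row * plot_spec.row_spacing
        has_gap = rng.random() < plot_spec.gap_probability
        gap_start = (
            float(rng.uniform(0, max(plot_spec.row_length - plot_spec.gap_span, 0.0)))
            if has_gap
            else -1.0
        )
        x = 0.0
        while x <= plot_spec.row_length + 1e-9:
            in_gap = has_gap and gap_start <= x <= gap_start + plot_spec.gap_span
            if not in_gap:
                placed = False
                for _ in range(plot_spec.max_retries):
                    cand = _draw_plant(plot_spec, rng)
                    yaw = float(rng.normal(0.0, 0.2))
                    ty = y0 + float(rng.uniform(-plot_spec.y_jitter, plot_spec.y_jitter))
                    cand = cand.transformed(yaw, np.array([x, ty, 0.0]))
                    if not any(_plants_overlap(cand, p) for p in plants):
                        plants.append(cand)
                        placed = True
                        break
                if not placed:
                    rejected += 1
                    log.warning("slot at x=%.3f left empty after retry cap", x)
            step = float(rng.uniform(*plot_spec.spacing_range))
            spacings.append(step)
            x += step
    return Scene(plants=plants, plot_spec=plot_spec, spacings=spacings,
                 n_rejected_slots=rejected)


def sample_scene(scene: Scene, total_points: int) -> AnnotatedCloud:
    """Draw exactly ``total_points`` labelled points, area-proportionally.

    Every point inherits the semantic class of the surface it was drawn
    from, and panicle points inherit the plant's instance id.  Sampling uses
    the scene rng stream held by the caller via ``scene_rng``; pass one
    explicitly through :func:`sample_scene_rng` for reproducibility.
    """
    return sample_scene_rng(scene, total_points, np.random.default_rng(0))


def sample_scene_rng(
    scene: Scene, total_points: int, rng: np.random.Generator
) -> AnnotatedCloud:
    if total_points < 1:
        raise ValueError(f"total_points must be >= 1, got {total_points}")
    tris, sems, insts = scene.labelled_triangles()
    pts, tri_idx = sample_surface(tris, total_points, rng)
    return AnnotatedCloud(coords=pts, semantic=sems[tri_idx], instance=insts[tri_idx])


def assign_size_class(box_dims: np.ndarray, cuts: np.ndarray | None = None) -> int:
    """Size class of one box from the mean of its dimensions.

    Bins the mean extent against three cut points spanning the template
    pool's dimension range; a mean exactly on a cut falls in the lower bin.
    """
    dims = np.asarray(box_dims, dtype=float).reshape(3)
    if np.any(dims <= 0):
        raise ValueError(f"box dims must be positive, got {dims}")
    if cuts is None:
        cuts, _ = size_class_table()
    return int(assign_size_class_array(dims.mean(), cuts))


def finalize_cloud(
    cloud: AnnotatedCloud,
    n_out: int = 100_000,
    pool: tuple[PanicleTemplate, ...] | None = None,
    min_points: int = MIN_POINTS_PER_BOX,
    box_margin: float = 0.006,
) -> AnnotatedCloud:
    """Upper-canopy crop, FPS downsampling, and per-instance box annotation.

    Points below the midpoint of the cloud's z range are discarded (the
    lower canopy carries no panicles by construction), survivors are
    FPS-downsampled to exactly ``n_out`` points, and each surviving panicle
    instance with at least ``min_points`` points receives one fitted
    oriented box and a size class.  ``box_margin`` (metres) inflates each
    fitted box the way a human annotator leaves slack around an instance;
    it also keeps boundary points inside the box under annotation-scale
    coordinate noise.
    """
    if cloud.n_points == 0:
        raise ValueError("cannot finalize an empty cloud")
    z = cloud.coords[:, 2]
    z_mid = 0.5 * (z.min() + z.max())
    keep = np.nonzero(z >= z_mid)[0]
    if n_out > keep.size:
        raise ValueError(
            f"n_out={n_out} exceeds the {keep.size} points surviving the "
            f"upper-canopy crop (of {cloud.n_points} total)"
        )
    sub = keep[farthest_point_sample(cloud.coords[keep], n_out)]
    out = cloud.select(sub)
    cuts, _ = size_class_table(pool)
    boxes, size_classes, box_ids = [], [], []
    ids, counts = np.unique(out.instance[out.instance >= 0], return_counts=True)
    for iid, cnt in zip(ids, counts):
        if cnt < min_points:
            continue
        box = fit_instance_box(out.instance_points(int(iid)))
        box.dims = box.dims + 2 * box_margin
        boxes.append(box)
        size_classes.append(assign_size_class(box.dims, cuts))
        box_ids.append(int(iid))
    out.boxes = boxes
    out.size_classes = np.asarray(size_classes, dtype=int)
    out.box_instance_ids = np.asarray(box_ids, dtype=int)
    return out


def generate_dataset(
    n_scenes: int,
    base_seed: int,
    out_dir: str | Path,
    plot_spec: PlotSpec | None = None,
    n_points: int = 100_000,
) -> dict:
    """Generate ``n_scenes`` finalized plot clouds plus a manifest.

    Per-scene rngs are spawned deterministically from ``base_seed``; the
    same seed therefore reproduces byte-identical cloud, annotation and
    manifest files.  Each scene is written as ``scene_XXXX.ply`` (points +
    labels) and ``scene_XXXX.json`` (boxes), with ``manifest.json``
    recording specs, seeds, spacings and counts.
    """
    if n_scenes < 1:
        raise ValueError(f"n_scenes must be >= 1, got {n_scenes}")
    spec = plot_spec if plot_spec is not None else PlotSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(base_seed).spawn(n_scenes)
    manifest: dict = {
        "base_seed": int(base_seed),
        "n_scenes": int(n_scenes),
        "n_points": int(n_points),
        "plot_spec": {
            "row_length": spec.row_length,
            "spacing_range": list(spec.spacing_range),
            "n_rows": spec.n_rows,
            "gap_probability": spec.gap_probability,
            "gap_span": spec.gap_span,
            "templates": [t.morphology_class for t in spec.template_pool],
        },
        "scenes": [],
    }
    for i in range(n_scenes):
        rng = np.random.default_rng(children[i])
        scene = place_plants(spec, rng)
        tris, _, _ = scene.labelled_triangles()
        flat = tris.reshape(-1, 3)
        z_lo, z_hi = flat[:, 2].min(), flat[:, 2].max()
        # estimate the surviving area fraction to budget the pre-crop draw
        z_mid = 0.5 * (z_lo + z_hi)
        centroids = tris.mean(axis=1)[:, 2]
        areas = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        )
        frac = max(areas[centroids >= z_mid].sum() / areas.sum(), 0.05)
        total = int(n_points / frac * 1.2)
        final = None
        for _ in range(4):
            cloud = sample_scene_rng(scene, total, rng)
            try:
                final = finalize_cloud(cloud, n_points, pool=spec.template_pool)
                break
            except ValueError:
                total *= 2
        if final is None:
            raise RuntimeError(f"scene {i}: could not satisfy n_points={n_points}")
        stem = f"scene_{i:04d}"
        write_ply(out / f"{stem}.ply", final.coords, final.semantic, final.instance)
        write_annotations(
            out / f"{stem}.json",
            final.boxes,
            size_classes=list(final.size_classes),
            instance_ids=list(final.box_instance_ids),
        )
        manifest["scenes"].append(
            {
                "file": f"{stem}.ply",
                "annotations": f"{stem}.json",
                "seed_spawn_key": [int(k) for k in children[i].spawn_key],
                "n_plants": len(scene.plants),
                "n_boxes": len(final.boxes),
                "n_rejected_slots": scene.n_rejected_slots,
                "spacings_m": [round(s, 6) for s in scene.spacings],
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
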