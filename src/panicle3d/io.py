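"""Reading and writing labelled point clouds and box annotations.

Clouds travel as ASCII PLY with per-point ``x y z semantic_label
instance_id`` properties; box annotations as JSON listing, per panicle
instance, the oriented box (center, dims, yaw), its size class and the
instance id.  Plain whitespace-delimited XYZ(+label) text is accepted too.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import OrientedBox

__all__ = [
    "write_ply",
    "read_ply",
    "read_xyz",
    "write_annotations",
    "read_annotations",
]

_PLY_HEADER = """ply
format ascii 1.0
comment panicle3d labelled canopy cloud
element vertex {n}
property float x
property float y
property float z
property int semantic_label
property int instance_id
end_header
"""


def write_ply(
    path: str | Path,
    coords: np.ndarray,
    semantic_labels: np.ndarray | None = None,
    instance_ids: np.ndarray | None = None,
) -> None:
    """Write a labelled cloud as ASCII PLY (labels default to -1)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    sem = (
        np.full(n, -1, dtype=int)
        if semantic_labels is None
        else np.asarray(semantic_labels, dtype=int).reshape(n)
    )
    inst = (
        np.full(n, -1, dtype=int)
        if instance_ids is None
        else np.asarray(instance_ids, dtype=int).reshape(n)
    )
    lines = [_PLY_HEADER.format(n=n)]
    for i in range(n):
        lines.append(
            f"{coords[i, 0]:.6f} {coords[i, 1]:.6f} {coords[i, 2]:.6f} "
            f"{sem[i]} {inst[i]}\n"
        )
    Path(path).write_text("".join(lines))


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an ASCII PLY written by :func:`write_ply`.

    Returns ``(coords, semantic_labels, instance_ids)``; label columns that
    are absent from the header come back filled with -1.
    """
    text = Path(path).read_text()
    if not text.startswith("ply"):
        raise ValueError(f"{path}: not a PLY file")
    header, _, body = text.partition("end_header\n")
    n = None
    props: list[str] = []
    for line in header.splitlines():
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n = int(parts[2])
        elif parts and parts[0] == "property" and n is not None:
            props.append(parts[2])
    if n is None:
        raise ValueError(f"{path}: no vertex element in header")
    data = np.loadtxt(body.splitlines(), dtype=float, ndmin=2)
    if data.shape[0] != n:
        raise ValueError(f"{path}: header promises {n} vertices, body has {data.shape[0]}")
    cols = {name: data[:, i] for i, name in enumerate(props)}
    coords = np.column_stack([cols["x"], cols["y"], cols["z"]])
    sem = cols.get("semantic_label", np.full(n, -1.0)).astype(int)
    inst = cols.get("instance_id", np.full(n, -1.0)).astype(int)
    return coords, sem, inst


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read whitespace-delimited ``x y z [semantic [instance]]`` text."""
    data = np.loadtxt(Path(path), dtype=float, ndmin=2)
    if data.shape[1] < 3:
        raise ValueError(f"{path}: need at least 3 columns, got {data.shape[1]}")
    n = data.shape[0]
    sem = data[:, 3].astype(int) if data.shape[1] > 3 else np.full(n, -1, dtype=int)
    inst = data[:, 4].astype(int) if data.shape[1] > 4 else np.full(n, -1, dtype=int)
    return data[:, :3], sem, inst


def write_annotations(
    path: str | Path,
    boxes: list[OrientedBox],
    size_classes: list[int] | None = None,
    instance_ids: list[int] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write oriented-box annotations (or scored detections) as JSON."""
    records = []
    for i, box in enumerate(boxes):
        rec = box.to_dict()
        rec["size_class"] = int(size_classes[i]) if size_classes is not None else -1
        rec["instance_id"] = int(instance_ids[i]) if instance_ids is not None else i
        if scores is not None:
            rec["score"] = float(scores[i])
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_annotations(
    path: str | Path,
) -> tuple[list[OrientedBox], np.ndarray, np.ndarray, np.ndarray]:
    """Read annotation JSON -> (boxes, size_classes, instance_ids, scores).

    Scores default to 1.0 when absent (ground-truth files carry none).
    """
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a JSON list of box records")
    boxes = [OrientedBox.from_dict(r) for r in records]
    size_classes = np.array([r.get("size_class", -1) for r in records], dtype=int)
    instance_ids = np.array(
        [r.get("instance_id", i) for i, r in enumerate(records)], dtype=int
    )
    scores = np.array([r.get("score", 1.0) for r in records], dtype=float)
    return boxes, size_classes, instance_ids, scores
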