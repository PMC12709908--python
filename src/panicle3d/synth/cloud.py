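"""The annotated point-cloud container shared by the generator, augmentation
and the model: coordinates, per-point semantic/instance labels, oriented
boxes for panicle instances, and per-box size classes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import PANICLE, OrientedBox

__all__ = ["AnnotatedCloud"]


@dataclass
class AnnotatedCloud:
    """Labelled canopy point cloud with panicle instance boxes.

    ``semantic`` holds class codes {panicle=0, stem=1, leaf=2}; ``instance``
    is a panicle instance id (>= 0) for panicle points and -1 elsewhere.
    ``boxes[i]`` annotates the instance ``box_instance_ids[i]`` and carries
    size class ``size_classes[i]``.
    """

    coords: np.ndarray
    semantic: np.ndarray
    instance: np.ndarray
    boxes: list[OrientedBox] = field(default_factory=list)
    size_classes: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    box_instance_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.semantic = np.asarray(self.semantic, dtype=int).reshape(n)
        self.instance = np.asarray(self.instance, dtype=int).reshape(n)
        self.size_classes = np.asarray(self.size_classes, dtype=int).reshape(-1)
        self.box_instance_ids = np.asarray(self.box_instance_ids, dtype=int).reshape(-1)
        if len(self.boxes) != self.size_classes.shape[0] or len(
            self.boxes
        ) != self.box_instance_ids.shape[0]:
            raise ValueError("boxes, size_classes and box_instance_ids must align")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def select(self, mask_or_index: np.ndarray) -> "AnnotatedCloud":
        """Point-wise subset; boxes are carried over unchanged."""
        return AnnotatedCloud(
            coords=self.coords[mask_or_index],
            semantic=self.semantic[mask_or_index],
            instance=self.instance[mask_or_index],
            boxes=list(self.boxes),
            size_classes=self.size_classes.copy(),
            box_instance_ids=self.box_instance_ids.copy(),
        )

    def copy(self) -> "AnnotatedCloud":
        return AnnotatedCloud(
            coords=self.coords.copy(),
            semantic=self.semantic.copy(),
            instance=self.instance.copy(),
            boxes=[OrientedBox(b.center.copy(), b.dims.copy(), b.yaw) for b in self.boxes],
            size_classes=self.size_classes.copy(),
            box_instance_ids=self.box_instance_ids.copy(),
        )

    def instance_points(self, instance_id: int) -> np.ndarray:
        return self.coords[self.instance == instance_id]

    def audit(self, min_points: int = 50, box_coverage: float = 0.95) -> list[str]:
        """Check the container invariants; returns a list of violations.

        Checks: semantic "panicle" <=> instance id >= 0; every instance with
        at least ``min_points`` points has exactly one box; each box contains
        at least ``box_coverage`` of its instance's points; size classes lie
        in {0, 1, 2, 3}.
        """
        errs: list[str] = []
        pan = self.semantic == PANICLE
        if not np.array_equal(pan, self.instance >= 0):
            errs.append("panicle label and instance id >= 0 do not coincide")
        ids, counts = np.unique(self.instance[self.instance >= 0], return_counts=True)
        boxed = set(int(i) for i in self.box_instance_ids)
        if len(boxed) != len(self.box_instance_ids):
            errs.append("duplicate boxes for one instance")
        for iid, cnt in zip(ids, counts):
            if cnt >= min_points and int(iid) not in boxed:
                errs.append(f"instance {iid} has {cnt} points but no box")
        for box, iid in zip(self.boxes, self.box_instance_ids):
            pts = self.instance_points(int(iid))
            if pts.shape[0] == 0:
                errs.append(f"box for instance {iid} has no points in the cloud")
                continue
            frac = box.contains(pts).mean()
            if frac < box_coverage:
                errs.append(
                    f"box for instance {iid} covers only {frac:.2%} of its points"
                )
        if self.size_classes.size and (
            self.size_classes.min() < 0 or self.size_classes.max() > 3
        ):
            errs.append("size classes outside {0,1,2,3}")
        return errs
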