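"""Parameter templates for procedural sorghum organs and plot layouts.

Templates are decimetre-scale (all lengths in metres, z-up) so that the
organ dimensions match the neighbourhood radii the detection network uses.
A plot's "type" is expressed as the pool of panicle templates it samples
from: a pool of open templates yields an open-panicle plot, a mixed pool a
heterogeneous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PanicleTemplate",
    "StemSpec",
    "LeafSpec",
    "PlotSpec",
    "default_template_pool",
    "size_class_table",
]


@dataclass(frozen=True)
class PanicleTemplate:
    """Morphological template for one panicle class.

    ``length`` is the rachis-aligned (vertical) extent and ``max_width`` the
    maximal horizontal diameter of the branch envelope.  ``branch_elevation``
    is the upward tilt of primary branches from horizontal, radians: compact
    heads hold branches steeply appressed, open heads spread them out.
    ``branch_peak`` locates the widest whorl as a fraction of length from
    the base; ``taper`` shrinks branch length toward the tip.
    """

    morphology_class: str
    length: float
    max_width: float
    branch_elevation: float
    branch_peak: float = 0.3
    taper: float = 0.15
    n_whorls: int = 14
    branches_per_whorl: int = 5
    peduncle_radius: float = 0.010
    point_density: float = 40000.0  # points/m^2, used for density heuristics

    def __post_init__(self) -> None:
        if self.length <= 0 or self.max_width <= 0:
            raise ValueError(
                f"length and max_width must be > 0, got {self.length}, {self.max_width}"
            )
        if self.peduncle_radius <= 0:
            raise ValueError("peduncle_radius must be > 0")

    @property
    def nominal_dims(self) -> np.ndarray:
        """(dx, dy, dz) of the nominal bounding box for this template."""
        return np.array([self.max_width, self.max_width, self.length])

    def jittered(self, rng: np.random.Generator, rel: float = 0.1) -> "PanicleTemplate":
        """Resample length/width within +-``rel`` relative jitter."""
        return PanicleTemplate(
            morphology_class=self.morphology_class,
            length=self.length * float(rng.uniform(1 - rel, 1 + rel)),
            max_width=self.max_width * float(rng.uniform(1 - rel, 1 + rel)),
            branch_elevation=self.branch_elevation,
            branch_peak=self.branch_peak,
            taper=self.taper,
            n_whorls=self.n_whorls,
            branches_per_whorl=self.branches_per_whorl,
            peduncle_radius=self.peduncle_radius * float(rng.uniform(0.95, 1.05)),
            point_density=self.point_density,
        )


@dataclass(frozen=True)
class StemSpec:
    """Chained-internode stem: lengths in metres, summing to the stem height.

    ``curvature`` is the lateral tip offset per unit height (dimensionless);
    ``top_radius`` should sit within 10% of the panicle's peduncle radius so
    the stem thickness is consistent with the head it carries.
    """

    internode_lengths: tuple[float, ...]
    base_radius: float = 0.016
    top_radius: float = 0.010
    curvature: float = 0.02

    def __post_init__(self) -> None:
        if len(self.internode_lengths) < 1 or any(
            l <= 0 for l in self.internode_lengths
        ):
            raise ValueError("internode lengths must be positive")
        if self.base_radius <= 0 or self.top_radius <= 0:
            raise ValueError("stem radii must be > 0")

    @property
    def n_internodes(self) -> int:
        return len(self.internode_lengths)

    @property
    def height(self) -> float:
        return float(sum(self.internode_lengths))


@dataclass(frozen=True)
class LeafSpec:
    """Single leaf blade: drooping ribbon grafted at an internode junction."""

    blade_length: float = 0.45
    max_blade_width: float = 0.06
    midrib_curvature: float = 1.4  # total downward bend along the midrib, radians
    attachment_index: int = 0

    def __post_init__(self) -> None:
        if self.blade_length <= 0 or self.max_blade_width <= 0:
            raise ValueError("blade length and width must be > 0")


@dataclass(frozen=True)
class PlotSpec:
    """Layout of one synthetic single-row plot.

    Defaults emulate research-plot conditions: a 4 m single row with plant
    spacing drawn uniformly in [5, 15] cm, occasionally interrupted by a
    contiguous empty span (failed establishment).
    """

    row_length: float = 4.0
    spacing_range: tuple[float, float] = (0.05, 0.15)
    n_rows: int = 1
    row_spacing: float = 0.75
    gap_probability: float = 0.15
    gap_span: float = 0.4
    stem_height_range: tuple[float, float] = (0.9, 1.2)
    n_leaves_range: tuple[int, int] = (4, 7)
    y_jitter: float = 0.015
    max_retries: int = 8
    template_pool: tuple[PanicleTemplate, ...] = field(
        default_factory=lambda: tuple(default_template_pool())
    )

    def __post_init__(self) -> None:
        lo, hi = self.spacing_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid spacing range {self.spacing_range}")
        if self.row_length <= hi:
            raise ValueError("row_length must exceed the maximum spacing")
        if len(self.template_pool) == 0:
            raise ValueError("template pool must be non-empty")


def default_template_pool() -> list[PanicleTemplate]:
    """The four morphology classes used to compose plot types.

    Dimensions span the emergence-to-maturity range seen in field sorghum:
    small emerging heads (~12 cm) up to open mature heads (~28 cm long,
    14 cm wide).  Width/length ratio rises monotonically from emerging and
    compact to open morphologies.
    """
    return [
        PanicleTemplate(
            "emerging", length=0.12, max_width=0.04, branch_elevation=np.deg2rad(72),
            n_whorls=9, branches_per_whorl=4, peduncle_radius=0.007,
        ),
        PanicleTemplate(
            "compact", length=0.22, max_width=0.07, branch_elevation=np.deg2rad(62),
            n_whorls=14, branches_per_whorl=5, peduncle_radius=0.010,
        ),
        PanicleTemplate(
            "semi-open", length=0.25, max_width=0.10, branch_elevation=np.deg2rad(48),
            n_whorls=15, branches_per_whorl=5, peduncle_radius=0.011,
        ),
        PanicleTemplate(
            "open", length=0.28, max_width=0.14, branch_elevation=np.deg2rad(34),
            n_whorls=16, branches_per_whorl=6, peduncle_radius=0.012,
        ),
    ]


def size_class_table(
    pool: tuple[PanicleTemplate, ...] | list[PanicleTemplate] | None = None,
    jitter_rel: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Size-class cut points and per-class mean box dimensions for a pool.

    Panicles are binned into four size classes by the mean of their box
    dimensions.  The three cut points split the pool's attainable mean-dim
    range (template nominals +- the generator's jitter) into four equal
    bins; the mean dims exported per class parameterise the detection
    head's size decoding.  A value exactly on a cut belongs to the lower bin.

    Returns
    -------
    cuts : (3,) ndarray
    mean_dims : (4, 3) ndarray
    """
    if pool is None:
        pool = default_template_pool()
    means = np.array([t.nominal_dims.mean() for t in pool])
    lo = means.min() * (1 - jitter_rel)
    hi = means.max() * (1 + jitter_rel)
    cuts = lo + (hi - lo) * np.array([0.25, 0.5, 0.75])
    # representative dims per bin: average the templates whose nominal mean
    # falls in the bin; an empty bin borrows dims interpolated along the pool
    nominal = np.stack([t.nominal_dims for t in pool])
    mean_dims = np.empty((4, 3))
    for c in range(4):
        in_bin = assign_size_class_array(means, cuts) == c
        if in_bin.any():
            mean_dims[c] = nominal[in_bin].mean(axis=0)
        else:
            target = lo + (hi - lo) * (c + 0.5) / 4.0
            j = int(np.argmin(np.abs(means - target)))
            mean_dims[c] = nominal[j] * (target / means[j])
    return cuts, mean_dims


def assign_size_class_array(mean_dims: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Vectorised size-class binning; a value on a cut goes to the lower bin."""
    return np.searchsorted(np.asarray(cuts), np.asarray(mean_dims), side="left")
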