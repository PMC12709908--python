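# Methods

This note documents the models and procedures implemented in `panicle3d`,
the assumptions behind them, the defaults that matter, and what the
synthetic experiments do and do not demonstrate.

## Problem setting

Sorghum yield phenotyping needs per-plot counts and size distributions of
panicles — the grain-bearing heads at the top of each plant.  Modern UAV
pipelines reconstruct field plots as dense 3D point clouds (photogrammetry
or radiance-field exports) in which panicles appear as compact blobs above
a tangle of leaves and stems, with no reliable colour channel.  The package
treats the problem as joint semantic segmentation (panicle / stem / leaf
per point) and 3D oriented-box detection on raw XYZ point clouds, trained
entirely on procedurally generated labelled canopies.

## Flight-plan calculators

Three closed forms support capture planning for video-based acquisition:
motion blur `speed x shutter` (mm), whole frames `floor(duration x fps)`,
and ground sampling distance under a nadir pinhole model
`2 h tan(fov/2) / width_px` (cm/pixel).  The GSD convention is documented
rather than matched to any vendor datasheet: published per-sensor GSD
figures depend on the effective focal length and video crop mode, which
are rarely stated, so the calculator's number is the convention's number.
Frame counts floor rather than round because a partial frame is never
written.

## Synthetic canopy generator

The generator emulates single-row research plots: a 4 m row, plant spacing
drawn uniformly in [5, 15] cm, occasional contiguous unplanted spans
(establishment gaps), and per-plot "types" expressed as the pool of
panicle templates a plot samples from.

**Organs.**  Panicles are whorled branch tubes around a bowed, tapering
rachis.  Four morphology templates (emerging, compact, semi-open, open)
span roughly 12-28 cm lengths and 4-14 cm widths, with branch elevation
falling from ~72 to ~34 degrees as heads open; the widest whorl is placed
at 30 % of rachis height by a base-peaked envelope, so axis-aligned extents
land within 10 % of template length/width.  Stems are chains of internode
cylinders rescaled to reach the panicle base, with curvature realised as a
lateral offset growing quadratically with height and a top radius equal to
the peduncle radius.  Leaves are drooping blade ribbons with exact arc
length, grafted at internode junctions with alternating cross-row azimuths
(distichous phyllotaxy); keeping blades mostly across the row is what makes
5 cm spacings geometrically feasible without constant collisions.

**Placement and overlap.**  Plants are placed sequentially along the row;
a candidate whose triangles intersect an already-placed plant's triangles
(segment-triangle tests, AABB-prefiltered) is redrawn up to 8 times, after
which the slot stays empty.  Coplanar contact counts as non-intersecting —
a measure-zero case under jittered placement.  The zero-overlap contract is
re-audited independently in the tests.

**Sampling and finalization.**  Clouds are drawn area-proportionally over
all surface triangles, each point inheriting its surface's semantic class
and (for panicles) the plant's instance id.  Finalization crops everything
below the midpoint of the cloud's z range — stem heights (0.9-1.2 m) exceed
half the maximal plant height by construction, so every panicle point
survives — then farthest-point-samples survivors to exactly 100,000 points,
and fits one oriented box per surviving instance with at least 50 points
(smaller fragments keep labels but get no box, avoiding degenerate boxes).
Fitted boxes are the minimal-area rotated rectangle of the xy projection
plus the z extent, inflated by a 6 mm margin per side — the slack a human
annotator leaves, and three panicle-jitter sigmas, so augmented points stay
enclosed.

**Size classes.**  Panicles fall into four classes by the mean of their box
dims, binned against three cuts splitting the template pool's attainable
range into equal quarters (a value on a cut takes the lower bin).  The
per-class mean dims are exported to the detection head as the size-decoding
anchor; generator and model must share this table.

**What the generator does not emulate.**  Sensor noise, webbing artefacts
between adjacent heads, occlusion-dependent density falloff, lodging,
panicles sheathed in the flag leaf, and root/soil geometry.  Tests passing
on these clouds demonstrate that the architecture can learn the task and
that every contract holds; they do not quantify transfer to real UAV
reconstructions.

## Augmentation

Rotation is xy-plane only (gravity is meaningful), rescaling is uniform in
[0.85, 1.15] about the scene centroid so size-class labels stay valid, and
dropout removes each point independently with probability drawn from
[0.2, 0.5].  Jitter is class-aware: leaf sigma 10 mm versus 2 mm for
panicle and stem, so canopy clutter blurs while heads keep their shape; a
displaced non-panicle point may never land within 5 mm of a panicle point
(redrawn up to 10 times, else restored; points that already start inside
the shell, e.g. stem tops at the peduncle, are exempt).  Only the ordering
constraint (leaf > panicle = stem) is principled; the magnitudes are
documented defaults exposed in `AugmentConfig`.  No augmentation ever
touches a label.  The composition order rotate -> rescale -> jitter ->
dropout -> shuffle is fixed, making the chain a pure function of
(cloud, config, seed).

## SegVoteNet

**Encoder.**  Four set-abstraction layers sample 2560 / 1024 / 512 / 256
points by farthest-point sampling and pool neighbourhood features through
shared MLPs.  The first two layers use multi-scale grouping (ball radii
0.05+0.1 and 0.1+0.2 m, group sizes 128+64 and 64+32, MLPs [16,16,32] per
scale and [32,32,64]/[64,64,128]); the last two use single 0.4 and 0.8 m
queries with [128,128,256] MLPs, giving 256-point output with 256-length
features.  Radii are panicle-scale by design.  Group coordinates enter as
center-relative offsets concatenated to features (the raw-vs-centered
choice is not dictated anywhere; centered is the convention here).  FPS
starts at the lexicographically smallest point, which makes sampling
deterministic and invariant to input order; ties break to the lowest index.
Inputs smaller than a layer's sample count clamp that layer (small fixtures
remain usable).

**Segmentation branch.**  Four feature-propagation layers (inverse-distance
interpolation with k = 3, delta = 1e-8, skip-concatenated encoder features,
[256,256] shared MLPs) restore full cardinality; a [256,256,3] classifier
emits per-point logits.  The loss is weighted cross-entropy with 0.3
(panicle) / 0.6 (stem) / 0.1 (leaf), normalised by point count so each
class's contribution is linear in its weight — stems are sparse and leaves
dominate, and the weights rebalance exactly that.

**Detection branch.**  Seeds are FPS-sampled only from points the
segmentation branch labels panicle (with-replacement top-up when fewer than
`n_seeds` exist; a flagged fallback to all points when none do).  Seed
features come from a set-abstraction over the final FP layer using a
cylinder query — a 0.075 m circle in xy extended over the full z range —
with predicted labels appended one-hot; cylinders suit the vertical
panicle-over-stem geometry and pull in supporting stem context regardless
of depth.  A [256,256] PointNet then a [256,256] voting MLP emit exactly
two votes per seed (a learned center offset added to the seed position,
plus a vote feature).  Vote aggregation FPS-selects proposal centers,
groups votes in 0.1 m cylinders, pools with a [256,128,128] PointNet, and
shared heads predict objectness, a center refinement, 4 size-class logits
with per-class residuals (decoded as `mean_dims x (1 + residual)`, residual
clipped to [-0.9, 3] so dims stay positive), and 12 heading bins with
residuals.  `n_seeds` = 1024, `n_proposals` = 256 and 12 heading bins are
deep-Hough-voting conventions scaled to a single target class; the cylinder
group sizes (32 and 16) are likewise documented defaults.

**Losses.**  Vote: L1 from each boxed-instance seed's best-of-two votes to
its instance's box center.  Objectness: cross-entropy with near/far
assignment at 0.15 / 0.3 m center distance (panicle-scale rather than
room-scale).  Center: smooth-L1 in both directions (positives to matched
centers, every GT center to its nearest proposal).  Size and heading:
cross-entropy plus smooth-L1 on the true class's residual.  Branch weights
are the voting-framework conventions (objectness 0.5, class terms 0.1,
regression terms 1.0) with segmentation weighted 1.0 — nothing prescribes
the inter-branch ratio, so equal weighting is the default config.

**Optimization.**  AdamW at 0.002, decayed by 0.1 at epochs 24 and 32,
batch size 8 (gradients averaged over the batch), every stochastic choice
seeded from one run seed.  Batch normalisation is deliberately omitted:
layers are bias+ReLU only, which trains stably at the batch sizes and
widths used here and keeps forward passes exactly deterministic.
Non-finite losses abort with the per-term breakdown.

**Inference.**  Decoded proposals are filtered before NMS: a proposal
survives only if at least one predicted-panicle point lies inside its box
center-cropped in xy to 20 % of the volume (x and y scaled by sqrt(0.2)),
then greedy NMS at IoU 0.25 (the looser of the two evaluation thresholds;
no NMS threshold is prescribed anywhere).  Point density is near-uniform by
construction, so an empty core reliably indicates a spurious box.

## Geometry kernels

Rotated-box IoU is exact: shapely polygon intersection of the two
bird's-eye footprints times the z-interval overlap (both boxes are upright,
so the decomposition is exact; no axis-aligned approximation).  NMS is
greedy by descending score with index tie-breaks.  Neighbourhood queries
run on k-d trees, keep the nearest `max_samples` members when over-full,
and pad short groups by repeating the first member while recording true
counts; a center with no neighbour is padded with its nearest source point
and count 0.  Box fitting uses shapely's minimum rotated rectangle
(rotating calipers) with yaw normalised to [-pi/2, pi/2), and refuses
degenerate (< 3 point or xy-collinear) inputs.

## Evaluation and morphometrics

Average precision uses score-descending greedy matching (one match per GT
box at IoU >= threshold, ties by index) and the all-point precision
envelope — the standard modern integration, since no 11-point rule is
prescribed.  Empty-vs-empty scores AP 1 by convention; missing predictions
against real ground truth score 0.  Segmentation accuracy is the unweighted
mean of per-class recalls (all-class mode) or panicle recall alone
(panicle-only mode, for data whose labels were interpolated from boxes).
Morphometrics per detection: height = z extent, length/width = larger and
smaller horizontal extents, radius = (length + width)/4, i.e. the mean
horizontal semi-axis — boxes carry no radial profile, so this is the
box-native radius definition.

## Problem sizes used in the shipped experiments

The acceptance script generates one full 4 m plot (~35-40 plants), samples
300k surface points, finalizes to 100,000, and runs the full-width encoder
on the result.  The test suite works at reduced scale as its own design
choice: a reduced-width model profile (widths x0.25, samples 512/256/128/64,
128 seeds, 32 proposals), short-row scenes of a few thousand points, a
400-step single-scene overfit for learnability, and a 200-step run over ten
generated scenes for loss-decrease.  Overfit detection quality is measured
as AP at IoU 0.25 on the training scene itself at a fixed seed; it is a
capacity/plumbing check, not a generalisation claim.

## Known limitations

- Organ geometry is procedural, not scanned: branch-level realism
  (spikelets, grain bulge, awns) is absent, and emerging heads sheathed in
  the flag leaf are not modelled at all.
- The numpy training loop is single-threaded and desk-scale; the
  full-width, 600-scene, 10k-epoch regime the architecture targets is out
  of reach here, and headline field mAP values are correspondingly not
  reproduced — only architecture contracts and scaled-down learnability.
- IoU/NMS are exact but O(n^2) in kept boxes; fine for hundreds of
  proposals, not for thousands.
- The merge-epsilon jitter constraint is enforced point-to-point, not
  surface-to-surface.
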