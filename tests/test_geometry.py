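"""Geometric kernels against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest

from panicle3d.geometry import (
    LEAF,
    PANICLE,
    OrientedBox,
    box_iou_3d,
    farthest_point_sample,
    fit_instance_box,
    inverse_distance_interpolate,
    nms_3d,
    occupancy_filter,
    radius_query,
)


def brute_force_fps(points, k, start):
    """Independent greedy FPS: explicit min-distance maximisation."""
    chosen = [start]
    while len(chosen) < k:
        d = np.min(
            np.linalg.norm(points[:, None, :] - points[chosen][None], axis=2), axis=1
        )
        chosen.append(int(np.argmax(d)))  # argmax picks lowest index on ties
    return chosen


class TestFPS:
    def test_collinear_pair(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        assert set(farthest_point_sample(pts, 2, 0)) == {0, 9}

    def test_collinear_triple_tie_break(self):
        # after {0, 9} both 4 and 5 are distance 4 from the nearer end;
        # the documented tie-break picks the lower index
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        assert list(farthest_point_sample(pts, 3, 0)) == [0, 9, 4]

    def test_exhaustive_case(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        idx = farthest_point_sample(pts, 8, 2)
        assert sorted(idx) == list(range(8))
        assert idx[0] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(60, 3))
        k = int(rng.integers(2, 30))
        got = list(farthest_point_sample(pts, k, 0))
        assert got == brute_force_fps(pts, k, 0)

    def test_prefix_stability(self, rng):
        pts = rng.normal(size=(100, 3))
        full = list(farthest_point_sample(pts, 50, 0))
        for j in (1, 10, 37):
            assert list(farthest_point_sample(pts, j, 0)) == full[:j]

    def test_k_out_of_range(self, rng):
        pts = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            farthest_point_sample(pts, 6)


class TestRadiusQuery:
    def test_sphere_basic(self):
        centers = np.zeros((1, 3))
        pts = np.array([[0.5, 0, 0], [1.5, 0, 0]])
        g = radius_query(centers, pts, 1.0, 4, "sphere")
        assert g.counts[0] == 1
        assert set(g.indices[0]) == {0}

    def test_cylinder_ignores_z(self):
        centers = np.zeros((1, 3))
        pts = np.array([[0.05, 0, 10.0]])
        sph = radius_query(centers, pts, 0.075, 4, "sphere")
        cyl = radius_query(centers, pts, 0.075, 4, "cylinder")
        assert sph.counts[0] == 0
        assert cyl.counts[0] == 1

    @pytest.mark.parametrize("mode", ["sphere", "cylinder"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, mode, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, size=(500, 3))
        centers = rng.uniform(-1, 1, size=(20, 3))
        r = 0.3
        big = 600  # no truncation: membership must match exactly
        g = radius_query(centers, pts, r, big, mode)
        for i, c in enumerate(centers):
            if mode == "sphere":
                d = np.linalg.norm(pts - c, axis=1)
            else:
                d = np.linalg.norm(pts[:, :2] - c[:2], axis=1)
            expected = set(np.nonzero(d <= r)[0])
            got = set(g.indices[i, : g.counts[i]])
            assert got == expected

    def test_padding_repeats_first_member(self):
        centers = np.zeros((1, 3))
        pts = np.array([[0.1, 0, 0], [5, 5, 5]])
        g = radius_query(centers, pts, 1.0, 4, "sphere")
        assert g.counts[0] == 1
        assert list(g.indices[0]) == [0, 0, 0, 0]

    def test_empty_source_flagged(self):
        g = radius_query(np.zeros((2, 3)), np.zeros((0, 3)), 1.0, 4)
        assert g.empty_source
        assert g.counts.sum() == 0

    def test_truncation_keeps_nearest(self):
        centers = np.zeros((1, 3))
        pts = np.column_stack([np.linspace(0.1, 0.9, 9), np.zeros(9), np.zeros(9)])
        g = radius_query(centers, pts, 1.0, 3, "sphere")
        assert set(g.indices[0]) == {0, 1, 2}


class TestInverseDistanceInterpolate:
    def test_constant_features(self, rng):
        src = rng.normal(size=(20, 3))
        tgt = rng.normal(size=(7, 3))
        feats = np.full((20, 4), 3.25)
        out = inverse_distance_interpolate(tgt, src, feats, k=3)
        assert np.allclose(out, 3.25)

    def test_coincident_target_dominated_by_source(self, rng):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        feats = np.array([5.0, -1.0, 2.0])
        out = inverse_distance_interpolate(src[:1], src, feats, k=3)
        assert out[0] == pytest.approx(5.0, abs=1e-6)

    def test_hand_example_two_sources(self):
        # distances 1 and 3, features 0 and 4, k=2 -> (1*0 + 1/3*4)/(4/3) = 1
        src = np.array([[1, 0, 0], [3, 0, 0.0]])
        feats = np.array([0.0, 4.0])
        out = inverse_distance_interpolate(np.zeros((1, 3)), src, feats, k=2)
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_k_clamped(self, rng):
        src = rng.normal(size=(2, 3))
        out = inverse_distance_interpolate(
            rng.normal(size=(3, 3)), src, np.ones(2), k=10
        )
        assert out.shape == (3,)


def mc_iou(a, b, n=1_000_000, seed=0):
    """Monte-Carlo IoU oracle by volume sampling over the joint AABB."""
    rng = np.random.default_rng(seed)
    corners = np.vstack([a.corners(), b.corners()])
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n, 3))
    in_a = a.contains(pts)
    in_b = b.contains(pts)
    inter = (in_a & in_b).mean()
    union = (in_a | in_b).mean()
    return inter / union


class TestBoxIoU:
    def test_identical(self):
        b = OrientedBox([1, 2, 3], [0.2, 0.1, 0.4], 0.3)
        assert box_iou_3d(b, b) == pytest.approx(1.0)

    def test_disjoint_z(self):
        a = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        b = OrientedBox([0, 0, 2], [1, 1, 1], 0)
        assert box_iou_3d(a, b) == 0.0

    def test_axis_aligned_offset_cubes(self):
        a = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        b = OrientedBox([0.5, 0, 0], [1, 1, 1], 0)
        assert box_iou_3d(a, b) == pytest.approx(1 / 3)

    def test_rotated_square_against_monte_carlo(self):
        a = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        b = OrientedBox([0, 0, 0], [1, 1, 1], math.pi / 4)
        assert box_iou_3d(a, b) == pytest.approx(mc_iou(a, b), abs=0.01)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_rotated_pairs_against_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        a = OrientedBox(rng.uniform(-0.2, 0.2, 3), rng.uniform(0.5, 1.5, 3),
                        rng.uniform(-math.pi, math.pi))
        b = OrientedBox(rng.uniform(-0.2, 0.2, 3), rng.uniform(0.5, 1.5, 3),
                        rng.uniform(-math.pi, math.pi))
        assert box_iou_3d(a, b) == pytest.approx(mc_iou(a, b, seed=seed), abs=0.01)

    def test_symmetry_and_rigid_invariance(self, rng):
        a = OrientedBox([0.3, -0.2, 0.1], [0.4, 0.2, 0.5], 0.7)
        b = OrientedBox([0.4, 0.0, 0.2], [0.3, 0.3, 0.4], -0.4)
        base = box_iou_3d(a, b)
        assert box_iou_3d(b, a) == pytest.approx(base)
        ang, t = 1.1, np.array([2.0, -3.0, 0.5])
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0], [math.sin(ang), math.cos(ang), 0],
             [0, 0, 1]]
        )
        a2 = OrientedBox(rot @ a.center + t, a.dims, a.yaw + ang)
        b2 = OrientedBox(rot @ b.center + t, b.dims, b.yaw + ang)
        assert box_iou_3d(a2, b2) == pytest.approx(base, abs=1e-9)


def reference_nms(boxes, scores, thr):
    """Exhaustive reference NMS (kept separate from the implementation)."""
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if box_iou_3d(boxes[i], boxes[j]) > thr:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def random_boxes(rng, n):
    return [
        OrientedBox(
            rng.uniform([-1, -1, 0], [1, 1, 1]),
            rng.uniform(0.2, 0.8, 3),
            rng.uniform(-math.pi, math.pi),
        )
        for _ in range(n)
    ]


class TestNMS:
    def test_single_box_kept(self):
        b = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        assert nms_3d([b], [0.5], 0.25) == [0]

    def test_duplicate_suppressed(self):
        b = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        kept = nms_3d([b, b], np.array([0.9, 0.8]), 0.25)
        assert kept == [0]

    def test_empty(self):
        assert nms_3d([], np.zeros(0), 0.25) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        boxes = random_boxes(rng, n)
        scores = rng.random(n)
        thr = float(rng.uniform(0.1, 0.6))
        assert nms_3d(boxes, scores, thr) == reference_nms(boxes, scores, thr)

    def test_kept_set_pairwise_iou_bounded(self, rng):
        boxes = random_boxes(rng, 40)
        scores = rng.random(40)
        kept = nms_3d(boxes, scores, 0.3)
        for a in kept:
            for b in kept:
                if a != b:
                    assert box_iou_3d(boxes[a], boxes[b]) <= 0.3


class TestOccupancyFilter:
    def test_center_point_kept(self):
        box = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        keep = occupancy_filter([box], np.zeros((1, 3)), np.array([PANICLE]), 0.2)
        assert keep[0]

    def test_outer_shell_removed(self):
        box = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        # core half-extent = sqrt(0.2)/2 ~ 0.2236; points just outside it
        edge = math.sqrt(0.2) / 2 + 0.01
        pts = np.array([[edge, 0, 0], [0, -edge, 0], [edge, edge, 0]])
        keep = occupancy_filter([box], pts, np.full(3, PANICLE), 0.2)
        assert not keep[0]

    def test_wrong_label_removed(self):
        box = OrientedBox([0, 0, 0], [1, 1, 1], 0)
        keep = occupancy_filter([box], np.zeros((1, 3)), np.array([LEAF]), 0.2)
        assert not keep[0]

    def test_fraction_one_is_containment(self, rng):
        box = OrientedBox([0, 0, 0], [1, 1, 2], 0.4)
        pts = rng.uniform(-1, 1, size=(200, 3))
        labels = np.full(200, PANICLE)
        keep = occupancy_filter([box], pts, labels, 1.0)
        assert keep[0] == box.contains(pts).any()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            occupancy_filter([], np.zeros((0, 3)), np.zeros(0), 0.0)


class TestFitInstanceBox:
    def test_axis_aligned_slab(self):
        xs, ys, zs = np.meshgrid(
            np.linspace(0, 0.4, 5), np.linspace(0, 0.2, 4), np.linspace(0, 0.6, 6)
        )
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        box = fit_instance_box(pts)
        assert sorted(np.round(box.dims, 6)) == pytest.approx([0.2, 0.4, 0.6])
        assert box.dims[2] == pytest.approx(0.6)
        assert abs(box.yaw) % (math.pi / 2) == pytest.approx(0.0, abs=1e-6)

    def test_rotated_slab_recovers_yaw_and_dims(self):
        xs, ys, zs = np.meshgrid(
            np.linspace(0, 0.4, 9), np.linspace(0, 0.2, 5), np.linspace(0, 0.3, 4)
        )
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        ang = math.radians(30)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0], [math.sin(ang), math.cos(ang), 0],
             [0, 0, 1]]
        )
        rpts = pts @ rot.T
        box = fit_instance_box(rpts)
        assert sorted(np.round(box.dims[:2], 6)) == pytest.approx([0.2, 0.4])
        # yaw matches 30 deg up to the rectangle's 90-degree symmetry
        residual = (box.yaw - ang) % (math.pi / 2)
        assert min(residual, math.pi / 2 - residual) == pytest.approx(0.0, abs=1e-6)
        assert box.contains(rpts).all()

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_instance_box(np.zeros((1, 3)))
        line = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError):
            fit_instance_box(line)
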