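"""SegVoteNet architecture contracts: encoder shapes, seed purity, voting,
aggregation, losses and inference."""

from dataclasses import replace

import numpy as np
import pytest

from panicle3d.geometry import LEAF, PANICLE
from panicle3d.model import (
    DetectHeadConfig,
    EncoderConfig,
    Forward,
    SALayerConfig,
    SegVoteNet,
    TrainConfig,
    small_profile,
)
from panicle3d.nn import Tensor


@pytest.fixture(scope="module")
def small_model():
    m = SegVoteNet(profile="small", seed=0)
    m._build()
    return m


@pytest.fixture(scope="module")
def forward_result(small_model, tiny_cloud):
    return small_model.forward(tiny_cloud.coords)


class TestEncoder:
    def test_level_cardinalities_follow_config(self, small_model, tiny_cloud):
        xyz, feats = small_model.encode(tiny_cloud.coords)
        expected = [l.n_sample for l in small_model.encoder_.layers]
        assert [x.shape[0] for x in xyz[1:]] == expected
        assert feats[-1].shape == (expected[-1], small_model.encoder_.out_dims[-1])

    def test_input_smaller_than_sample_count_clamps(self, small_model, rng):
        pts = rng.normal(size=(100, 3))
        xyz, _ = small_model.encode(pts)
        assert xyz[1].shape[0] == 100  # clamped to input size
        assert xyz[-1].shape[0] == 64

    def test_paper_config_counts_strictly_decrease(self):
        cfg = EncoderConfig()
        assert [l.n_sample for l in cfg.layers] == [2560, 1024, 512, 256]
        with pytest.raises(ValueError):
            EncoderConfig(
                layers=(
                    SALayerConfig(100, (0.1,), (8,), ((8, 8),)),
                    SALayerConfig(200, (0.1,), (8,), ((8, 8),)),
                    SALayerConfig(50, (0.1,), (8,), ((8, 8),)),
                    SALayerConfig(25, (0.1,), (8,), ((8, 8),)),
                )
            )

    def test_permutation_invariance_of_sampled_sets(self, small_model, rng):
        pts = rng.normal(size=(600, 3)) * 0.3
        xyz1, _ = small_model.encode(pts)
        perm = rng.permutation(600)
        xyz2, _ = small_model.encode(pts[perm])
        for a, b in zip(xyz1[1:], xyz2[1:]):
            sa = np.array(sorted(map(tuple, np.round(a, 9))))
            sb = np.array(sorted(map(tuple, np.round(b, 9))))
            assert np.allclose(sa, sb)


class TestSegmentation:
    def test_per_point_logits(self, forward_result, tiny_cloud):
        assert forward_result.seg_logits.shape == (tiny_cloud.n_points, 3)
        probs = np.exp(forward_result.seg_logits.log_softmax(axis=1).data)
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestSeedsAndVotes:
    def test_seed_purity(self, forward_result):
        pred = forward_result.pred_labels
        if not forward_result.seed_fallback:
            assert (pred[forward_result.seed_indices] == PANICLE).all()

    def test_exact_panicle_set_used_when_counts_match(self, small_model, rng):
        pts = rng.normal(size=(500, 3))
        n_seeds = small_model.detect_head_.n_seeds
        labels = np.full(500, LEAF)
        labels[:n_seeds] = PANICLE
        chosen, fallback = small_model.sample_seeds(pts, labels, n_seeds, rng)
        assert not fallback
        assert set(chosen) == set(range(n_seeds))

    def test_fallback_when_no_panicle_predictions(self, small_model, rng):
        pts = rng.normal(size=(300, 3))
        labels = np.full(300, LEAF)
        chosen, fallback = small_model.sample_seeds(pts, labels, 64, rng)
        assert fallback
        assert len(chosen) == 64

    def test_vote_multiplicity(self, forward_result):
        s = forward_result.seed_xyz.shape[0]
        assert forward_result.votes.shape == (s, 2, 3)

    def test_cylinder_grouping_ignores_depth(self, small_model, rng):
        from panicle3d.geometry import radius_query

        det = small_model.detect_head_
        seed = np.array([[0.0, 0.0, 1.0]])
        deep_stem_point = np.array([[0.01, 0.0, -5.0]])
        g = radius_query(seed, deep_stem_point, det.seed_radius, 4, det.grouping_mode)
        assert g.counts[0] == 1

    def test_zero_offset_head_emits_votes_at_seeds(self, tiny_cloud):
        m = SegVoteNet(profile="small", seed=1)
        m._build()
        m.modules_["vote_out"].w.data[:] = 0.0
        m.modules_["vote_out"].b.data[:] = 0.0
        fw = m.forward(tiny_cloud.coords)
        assert np.allclose(fw.votes.data, fw.seed_xyz[:, None, :])


class TestAggregation:
    def test_proposal_count(self, forward_result, small_model):
        assert (
            forward_result.proposal_centers.shape[0]
            == small_model.detect_head_.n_proposals
        )

    def test_two_clusters_get_one_proposal_each(self):
        enc, seg, det = small_profile(n_proposals=2)
        m = SegVoteNet(encoder=enc, seg_head=seg,
                       detect_head=replace(det, n_proposals=2), profile="small",
                       seed=0)
        m._build()
        # zero the refinement head so proposal centers equal selected votes
        m.modules_["head_out"].w.data[:] = 0.0
        m.modules_["head_out"].b.data[:] = 0.0
        rng = np.random.default_rng(0)
        c1, c2 = np.array([0.0, 0, 0]), np.array([5.0, 5, 0])
        votes = np.vstack([c1 + rng.normal(0, 0.02, (20, 3)),
                           c2 + rng.normal(0, 0.02, (20, 3))])
        feats = rng.normal(size=(40, m.detect_head_.seed_mlp[-1]))
        prop = m.aggregate_and_predict(Tensor(votes), Tensor(feats))
        centers = prop["centers"].data
        d1 = np.linalg.norm(centers - c1, axis=1)
        d2 = np.linalg.norm(centers - c2, axis=1)
        assert (d1 < 1).sum() == 1 and (d2 < 1).sum() == 1

    def test_decoded_dims_positive(self, small_model, forward_result):
        boxes, scores = small_model.decode_proposals(forward_result)
        assert all((b.dims > 0).all() for b in boxes)
        assert ((scores >= 0) & (scores <= 1)).all()


def _perfect_forward(model, cloud, n_seed_pts=8):
    """Construct a forward record whose predictions equal the targets."""
    det = model.detect_head_
    n = cloud.n_points
    seg_logits = Tensor(np.eye(3)[cloud.semantic] * 40.0 - 20.0)
    boxes = cloud.boxes
    centers = np.stack([b.center for b in boxes])
    p = len(boxes)
    # seeds on the first boxed instance; votes exactly at its center
    iid = int(cloud.box_instance_ids[0])
    seed_idx = np.nonzero(cloud.instance == iid)[0][:n_seed_pts]
    votes = np.repeat(centers[None, 0], 2 * len(seed_idx), 0).reshape(-1, 2, 3)
    mean_size = np.asarray(det.mean_size)
    size_cls = cloud.size_classes
    size_res = np.zeros((p, det.n_size_classes, 3))
    head_logits = np.full((p, det.n_heading_bins), -20.0)
    head_res = np.zeros((p, det.n_heading_bins))
    size_logits = np.full((p, det.n_size_classes), -20.0)
    for i, b in enumerate(boxes):
        size_logits[i, size_cls[i]] = 20.0
        size_res[i, size_cls[i]] = b.dims / mean_size[size_cls[i]] - 1.0
        hb, hr = model._heading_bin(b.yaw)
        head_logits[i, hb] = 20.0
        head_res[i, hb] = hr
    return Forward(
        coords=cloud.coords,
        sa_xyz=[],
        sa_feats=[],
        seg_logits=seg_logits,
        pred_labels=cloud.semantic.copy(),
        seed_indices=seed_idx,
        seed_xyz=cloud.coords[seed_idx],
        seed_fallback=False,
        votes=Tensor(votes),
        vote_feats=Tensor(np.zeros((len(seed_idx), 2, 4))),
        proposal_centers=Tensor(centers),
        objectness=Tensor(np.tile([-20.0, 20.0], (p, 1))),
        size_logits=Tensor(size_logits),
        size_residuals=Tensor(size_res),
        heading_logits=Tensor(head_logits),
        heading_residuals=Tensor(head_res),
    )


class TestLosses:
    def test_perfect_predictions_give_near_zero_losses(self, small_model, tiny_cloud):
        fw = _perfect_forward(small_model, tiny_cloud)
        losses = small_model.compute_losses(fw, tiny_cloud)
        for name, term in losses.items():
            assert float(term.data) <= 1e-6, f"{name} = {float(term.data)}"

    def test_random_init_losses_finite_and_positive(self, small_model, tiny_cloud,
                                                    forward_result):
        losses = small_model.compute_losses(forward_result, tiny_cloud)
        for name, term in losses.items():
            v = float(term.data)
            assert np.isfinite(v)
            assert v >= 0.0

    def test_every_branch_receives_gradient(self, tiny_cloud):
        m = SegVoteNet(profile="small", seed=3)
        m._build()
        fw = m.forward(tiny_cloud.coords)
        # ground truth placed at proposal centers so every term is active
        gt = tiny_cloud.copy()
        iids = [int(i) for i in gt.box_instance_ids[:2]]
        for k, iid in enumerate(iids):
            # near enough to count as positive, offset enough for nonzero loss
            gt.boxes[k].center = fw.proposal_centers.data[k] + np.array(
                [0.03, -0.02, 0.04]
            )
        gt.boxes = gt.boxes[: len(iids)]
        gt.size_classes = gt.size_classes[: len(iids)]
        gt.box_instance_ids = gt.box_instance_ids[: len(iids)]
        losses = m.compute_losses(fw, gt)
        branch_modules = {
            "segmentation": "classifier",
            "vote": "vote_out",
            "objectness": "head_out",
            "center": "head_out",
            "size_class": "head_out",
            "size_residual": "head_out",
            "heading_class": "head_out",
            "heading_residual": "head_out",
        }
        for name, modname in branch_modules.items():
            for p in m.params_:
                p.grad = None
            assert float(losses[name].data) > 0, f"{name} inactive"
            losses[name].backward()
            mod = m.modules_[modname]
            assert any(
                p.grad is not None and np.abs(p.grad).sum() > 0
                for p in mod.parameters()
            ), f"{name} has zero gradient into {modname}"

    def test_segmentation_loss_linear_in_class_weights(self, small_model, tiny_cloud,
                                                       forward_result):
        from panicle3d.model import SegHeadConfig

        base = small_model.compute_losses(forward_result, tiny_cloud)
        seg1 = float(base["segmentation"].data)
        # hand-computed stem contribution from the raw logits
        ls = forward_result.seg_logits.log_softmax(axis=1).data
        labels = tiny_cloud.semantic
        nll = -ls[np.arange(labels.size), labels]
        stem_part = 0.6 * nll[labels == 1].sum() / labels.size
        old = small_model.seg_head_
        try:
            small_model.seg_head_ = SegHeadConfig(
                fp_widths=old.fp_widths,
                classifier_widths=old.classifier_widths,
                class_weights=(0.3, 1.2, 0.1),
            )
            seg2 = float(
                small_model.compute_losses(forward_result, tiny_cloud)[
                    "segmentation"
                ].data
            )
        finally:
            small_model.seg_head_ = old
        assert seg2 - seg1 == pytest.approx(stem_part, rel=1e-9)


class TestSchedule:
    def test_multistep_decay(self):
        cfg = TrainConfig()
        assert cfg.lr_at(0) == pytest.approx(2e-3)
        assert cfg.lr_at(23) == pytest.approx(2e-3)
        assert cfg.lr_at(25) == pytest.approx(2e-4)
        assert cfg.lr_at(33) == pytest.approx(2e-5)

    def test_invalid_schedules(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0)
        with pytest.raises(ValueError):
            TrainConfig(decay_epochs=(32, 24))


class TestInference:
    def test_nms_contract(self, small_model, tiny_cloud):
        from panicle3d.geometry import box_iou_3d

        res = small_model.infer(tiny_cloud.coords, nms_iou=0.25, score_threshold=0.0)
        boxes = res["boxes"]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                assert box_iou_3d(boxes[i], boxes[j]) <= 0.25

    def test_no_panicle_predictions_no_detections(self, small_model, tiny_cloud,
                                                  monkeypatch):
        real_forward = small_model.forward

        def all_leaf_forward(coords, rng=None):
            fw = real_forward(coords, rng)
            fw.pred_labels = np.full(fw.pred_labels.shape, LEAF)
            return fw

        monkeypatch.setattr(small_model, "forward", all_leaf_forward)
        res = small_model.infer(tiny_cloud.coords, score_threshold=0.0)
        assert res["boxes"] == []

    def test_surviving_cores_contain_panicle_points(self, small_model, tiny_cloud):
        res = small_model.infer(tiny_cloud.coords, score_threshold=0.0)
        pan = res["labels"] == PANICLE
        core = np.sqrt(0.2)
        for box in res["boxes"]:
            assert box.contains(tiny_cloud.coords[pan], xy_scale=core).any()


class TestFitAndPersistence:
    def test_short_fit_records_history(self, tiny_cloud):
        m = SegVoteNet(
            profile="small", seed=0,
            train=TrainConfig(n_epochs=2, batch_size=1, input_points=800,
                              val_interval=1),
        )
        m.fit([tiny_cloud], validation=[tiny_cloud])
        assert m.n_steps_ == 2
        assert len(m.history_["loss"]) == 2
        assert len(m.history_["val"]) == 2
        assert all(np.isfinite(r["loss"]) for r in m.history_["loss"])
        assert "mAP@0.25" in m.history_["val"][0]

    def test_save_load_roundtrip(self, tmp_path, tiny_cloud):
        m = SegVoteNet(profile="small", seed=0)
        m._build()
        fw1 = m.forward(tiny_cloud.coords)
        m.save(tmp_path / "ckpt.npz")
        m2 = SegVoteNet.load(tmp_path / "ckpt.npz")
        fw2 = m2.forward(tiny_cloud.coords)
        assert np.allclose(fw1.seg_logits.data, fw2.seg_logits.data)
        assert np.allclose(fw1.proposal_centers.data, fw2.proposal_centers.data)

    def test_sklearn_params_roundtrip(self):
        m = SegVoteNet(profile="small", seed=7)
        params = m.get_params()
        assert params["seed"] == 7
        m.set_params(seed=9)
        assert m.seed == 9


class TestConfigValidation:
    def test_votes_per_seed_fixed_at_two(self):
        with pytest.raises(ValueError):
            DetectHeadConfig(votes_per_seed=3)

    def test_mean_size_alignment(self):
        with pytest.raises(ValueError):
            DetectHeadConfig(mean_size=((0.1, 0.1, 0.2),))
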