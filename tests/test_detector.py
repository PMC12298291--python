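"""Detector assembly: forward contracts, decoding/NMS, fusion wiring,
confidence scoring, training sanity and checkpoint round-trips."""
import numpy as np
import pytest

from iihgnn.autodiff import Tensor
from iihgnn.detector import (Detection, MitosisDetector, ModelConfig,
                             confidence_score, decode_and_nms,
                             evaluate_model, load_checkpoint, nms,
                             save_checkpoint, train_loop)


def tiny_cfg(**kw):
    kw.setdefault("widths", (4, 8, 12, 16, 20))
    kw.setdefault("input_size", 64)
    kw.setdefault("common_grid", (4, 4))
    return ModelConfig.reduced(**kw)


@pytest.fixture(scope="module")
def tiny_model():
    return MitosisDetector(tiny_cfg()).eval()


class TestForward:
    def test_deterministic_given_fixed_weights(self, tiny_model, rng):
        x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
        a = tiny_model(x)
        b = tiny_model(x)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_batch_independence_in_eval(self, tiny_model, rng):
        imgs = rng.random((2, 3, 64, 64)).astype(np.float32)
        both = tiny_model(Tensor(imgs))
        solo0 = tiny_model(Tensor(imgs[:1]))
        solo1 = tiny_model(Tensor(imgs[1:]))
        for rb, r0, r1 in zip(both, solo0, solo1):
            assert np.allclose(rb.data[0], r0.data[0], atol=1e-5)
            assert np.allclose(rb.data[1], r1.data[0], atol=1e-5)

    def test_all_zero_image_finite(self, tiny_model):
        raw = tiny_model(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert all(np.isfinite(r.data).all() for r in raw)

    def test_five_stage_pyramid_finite(self, rng):
        m = MitosisDetector(tiny_cfg(five_stage=True, input_size=128)).eval()
        raw = m(Tensor(rng.random((1, 3, 128, 128)).astype(np.float32)))
        shapes = [r.shape for r in raw]
        assert shapes == [(1, 7, 16, 16), (1, 7, 8, 8), (1, 7, 4, 4)]
        assert all(np.isfinite(r.data).all() for r in raw)

    @pytest.mark.parametrize("five_stage", [False, True])
    def test_full_size_input_finite_both_pyramids(self, five_stage):
        """A 640-px forward pass completes with finite outputs whether the
        pyramid uses pooled pads or real P6/P7 stages."""
        from iihgnn.autodiff import no_grad
        cfg = ModelConfig(input_size=640, five_stage=five_stage)
        m = MitosisDetector(cfg).eval()
        with no_grad():
            raw = m(Tensor(np.zeros((1, 3, 640, 640), np.float32)))
        assert [r.shape[-1] for r in raw] == [80, 40, 20]
        assert all(np.isfinite(r.data).all() for r in raw)

    def test_wrong_spatial_size_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model(Tensor(rng.random((1, 3, 32, 32)).astype(np.float32)))


class TestFusion:
    def test_gradient_reaches_p3_through_fusion(self, rng):
        m = MitosisDetector(tiny_cfg())
        m.train()
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        raw = m(x)
        sum(r.sum() for r in raw).backward()
        p3_conv = m.down2.conv.weight
        assert p3_conv.grad is not None
        assert np.abs(p3_conv.grad).max() > 0

    def test_zero_neck_reduces_to_backbone_path(self, tiny_model, rng):
        maps = [Tensor(rng.random((1, c, s, s)).astype(np.float32))
                for c, s in ((12, 8), (16, 4), (20, 2))]
        zeros = [Tensor(np.zeros_like(t.data)) for t in maps]
        fused = tiny_model.bottom_up_fuse(zeros, maps)
        plain = tiny_model.bottom_up_fuse(None, maps)
        for f, p in zip(fused, plain):
            assert np.allclose(f.data, p.data, atol=1e-6)

    def test_scale_mismatch_rejected(self, tiny_model, rng):
        maps = [Tensor(rng.random((1, c, s, s)).astype(np.float32))
                for c, s in ((12, 8), (16, 4), (20, 2))]
        bad = [maps[1], maps[0], maps[2]]
        with pytest.raises(ValueError):
            tiny_model.bottom_up_fuse(bad, maps)


class TestConfidence:
    @pytest.mark.parametrize("p,iou,expected",
                             [(1.0, 0.5, 0.5), (0.0, 0.7, 0.0),
                              (0.9, 0.8, 0.72)])
    def test_product(self, p, iou, expected):
        assert np.isclose(confidence_score(p, iou), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(1.2, 0.5)
        with pytest.raises(ValueError):
            confidence_score(0.5, -0.1)


class TestDecodeNMS:
    def test_duplicate_suppression(self):
        boxes = [(0, 0, 10, 10), (0, 0, 10, 10), (50, 50, 60, 60)]
        keep = nms(boxes, [0.9, 0.8, 0.7], iou_thresh=0.5)
        assert keep == [0, 2]

    def test_disjoint_all_kept(self):
        boxes = [(0, 0, 10, 10), (20, 20, 30, 30), (50, 50, 60, 60)]
        keep = nms(boxes, [0.5, 0.9, 0.7], iou_thresh=0.5)
        assert sorted(keep) == [0, 1, 2]

    def test_conf_threshold_one_empty(self, tiny_model, rng):
        raw = tiny_model(Tensor(rng.random((1, 3, 64, 64)).astype(np.float32)))
        cfg = tiny_cfg(conf_thresh=1.0)
        assert decode_and_nms(raw, cfg) == []

    def test_detections_sorted_and_non_overlapping(self, smoke_dataset):
        cfg = ModelConfig.reduced(conf_thresh=0.05)
        model = MitosisDetector(cfg).eval()
        x = Tensor((np.stack(smoke_dataset.images[:2]).astype(np.float32)
                    / 255).transpose(0, 3, 1, 2))
        raw = model(x)
        dets = decode_and_nms(raw, cfg)
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        from iihgnn.metrics import box_iou
        for i, a in enumerate(dets):
            for b in dets[i + 1:]:
                if a.class_id == b.class_id:
                    assert box_iou([a.box], [b.box])[0, 0] <= cfg.nms_iou

    def test_degenerate_detection_rejected(self):
        with pytest.raises(ValueError):
            Detection(box=(5, 5, 5, 10), class_id=0, confidence=0.5)
        with pytest.raises(ValueError):
            Detection(box=(0, 0, 5, 5), class_id=0, confidence=1.5)


class TestTraining:
    def test_loss_descends_on_learnable_task(self, smoke_dataset):
        data = (smoke_dataset.images[:8], smoke_dataset.annotations[:8])
        res = train_loop(data, tiny_cfg(input_size=128), seed=5,
                         iterations=20, batch_size=4)
        first = np.mean([l["total"] for l in res.log[:5]])
        last = np.mean([l["total"] for l in res.log[-5:]])
        assert last < first

    def test_same_seed_identical_trajectory(self, smoke_dataset):
        data = (smoke_dataset.images[:6], smoke_dataset.annotations[:6])
        cfg = tiny_cfg(input_size=128)
        log1 = train_loop(data, cfg, seed=3, iterations=5, batch_size=4).log
        log2 = train_loop(data, cfg, seed=3, iterations=5, batch_size=4).log
        assert [l["total"] for l in log1] == [l["total"] for l in log2]

    def test_checkpoint_round_trip_bit_identical(self, smoke_dataset,
                                                 tmp_path):
        data = (smoke_dataset.images[:6], smoke_dataset.annotations[:6])
        cfg = tiny_cfg(input_size=128)
        res = train_loop(data, cfg, seed=1, iterations=5, batch_size=4,
                         checkpoint=tmp_path / "w.npz")
        reloaded = load_checkpoint(tmp_path / "w.npz")
        x = Tensor((smoke_dataset.images[0].astype(np.float32) / 255)
                   .transpose(2, 0, 1)[None])
        a = res.model(x)
        b = reloaded(x)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)
        rep_a = evaluate_model(res.model, smoke_dataset.images[:4],
                               smoke_dataset.annotations[:4])
        rep_b = evaluate_model(reloaded, smoke_dataset.images[:4],
                               smoke_dataset.annotations[:4])
        assert rep_a["mAP50"] == rep_b["mAP50"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_loop(([], []), tiny_cfg(), iterations=1)
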