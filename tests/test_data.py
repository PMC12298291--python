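"""Tiling, annotation I/O and the synthetic patch generator."""
import numpy as np
import pytest
from scipy import ndimage

from iihgnn.data import (SynthConfig, boxes_coco_to_yolo, boxes_yolo_to_coco,
                         generate_synthetic_dataset, patch_wsi,
                         read_annotations, write_annotations)
from iihgnn.data.annotations import AnnotationFormatError
from iihgnn.data.synthetic import generate_synthetic_image


def brute_force_keep(box, patch_size, stride, H, W, min_vis=0.4):
    """Oracle: does `box` survive in at least one tile?"""
    def starts(extent):
        s = list(range(0, extent - patch_size + 1, stride))
        if not s or s[-1] != extent - patch_size:
            s.append(extent - patch_size)
        return s
    x0, y0, x1, y1 = box
    area = (x1 - x0) * (y1 - y0)
    count = 0
    for r0 in starts(H):
        for c0 in starts(W):
            ix0, iy0 = max(x0, c0), max(y0, r0)
            ix1 = min(x1, c0 + patch_size)
            iy1 = min(y1, r0 + patch_size)
            if ix1 > ix0 and iy1 > iy0 and \
                    (ix1 - ix0) * (iy1 - iy0) / area >= min_vis:
                count += 1
    return count


class TestPatchWsi:
    def test_2x2_grid_coordinates(self):
        img = np.zeros((1280, 1280, 3), dtype=np.uint8)
        box = ((690.0, 90.0, 710.0, 110.0), 0)   # centered at (700, 100)
        res = patch_wsi(img, [box], patch_size=640, stride=640)
        assert len(res.patches) == 4
        hits = [(p.origin, p.boxes) for p in res.patches if p.boxes]
        assert len(hits) == 1
        origin, boxes = hits[0]
        assert origin == (0, 640)                 # top-right tile
        (x0, y0, x1, y1), cls = boxes[0]
        assert (x0, y0, x1, y1) == (50.0, 90.0, 70.0, 110.0)
        assert x0 == 690 - 640

    def test_interior_box_appears_once(self, rng):
        img = np.zeros((512, 512), dtype=np.uint8)
        box = ((100.0, 100.0, 120.0, 130.0), 1)
        res = patch_wsi(img, [box], patch_size=256, stride=256)
        assert sum(len(p.boxes) for p in res.patches) == 1
        assert res.n_dropped == 0

    def test_conservation_against_oracle(self, rng):
        """Every source box is either kept in >= 1 patch or reported
        dropped, in exact agreement with a brute-force tile-intersection
        oracle."""
        H = W = 300
        img = np.zeros((H, W), dtype=np.uint8)
        for trial in range(10):
            boxes = []
            for _ in range(100):
                x0 = rng.uniform(0, W - 20)
                y0 = rng.uniform(0, H - 20)
                w = rng.uniform(4, 40)
                h = rng.uniform(4, 40)
                boxes.append(((x0, y0, min(x0 + w, W), min(y0 + h, H)), 0))
            res = patch_wsi(img, boxes, patch_size=128, stride=128)
            total_kept = sum(len(p.boxes) for p in res.patches)
            oracle_counts = [brute_force_keep(b, 128, 128, H, W)
                             for b, _ in boxes]
            assert total_kept == sum(oracle_counts)
            oracle_dropped = [i for i, c in enumerate(oracle_counts)
                              if c == 0]
            assert res.dropped == oracle_dropped

    def test_tiles_cover_full_extent(self):
        img = np.zeros((700, 900), dtype=np.uint8)
        res = patch_wsi(img, [], patch_size=256, stride=256)
        covered = np.zeros((700, 900), dtype=bool)
        for p in res.patches:
            r, c = p.origin
            covered[r:r + 256, c:c + 256] = True
        assert covered.all()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            patch_wsi(np.zeros((0, 0)), [], patch_size=1)


class TestAnnotationsIO:
    @pytest.mark.parametrize("fmt", ["coco", "yolo"])
    def test_round_trip(self, tmp_path, fmt):
        boxes = [((10.5, 20.25, 55.0, 61.75), 0), ((3.0, 4.0, 9.0, 8.0), 1)]
        path = tmp_path / f"ann.{fmt}"
        write_annotations(boxes, path, fmt, image_size=(128, 128))
        back = read_annotations(path, fmt, image_size=(128, 128))
        assert len(back) == 2
        for (b0, c0), (b1, c1) in zip(boxes, back):
            assert c0 == c1
            assert np.allclose(b0, b1, atol=1e-6)

    @pytest.mark.parametrize("fmt", ["coco", "yolo"])
    def test_empty_round_trip(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        write_annotations([], path, fmt, image_size=(64, 64))
        assert read_annotations(path, fmt, image_size=(64, 64)) == []

    def test_coco_yolo_conversion_identity(self):
        boxes = [((12.0, 8.0, 40.0, 30.0), 0), ((0.0, 0.0, 64.0, 64.0), 1)]
        size = (64, 64)
        there = boxes_coco_to_yolo(boxes, size)
        back = boxes_yolo_to_coco(there, size)
        for (b0, c0), (b1, c1) in zip(boxes, back):
            assert c0 == c1 and np.allclose(b0, b1, atol=1e-6)

    def test_malformed_yolo_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1 0.1\n0 0.2 nonsense\n")
        with pytest.raises(AnnotationFormatError, match=":2"):
            read_annotations(path, "yolo", image_size=(64, 64))


class TestSyntheticGenerator:
    def test_seed_determinism(self):
        cfg = SynthConfig.smoke(n_images=3, seed=9)
        a = generate_synthetic_dataset(cfg)
        b = generate_synthetic_dataset(cfg)
        for ia, ib in zip(a.images, b.images):
            assert np.array_equal(ia, ib)
        assert a.annotations == b.annotations
        assert a.splits == b.splits

    def test_mitosis_count_ranges(self):
        cfg = SynthConfig.smoke(n_images=10, seed=3)
        ds = generate_synthetic_dataset(cfg)
        total = 0
        for boxes in ds.annotations:
            n_mit = sum(1 for _, c in boxes if c == 0)
            assert 1 <= n_mit <= 3
            total += n_mit
        assert 10 <= total <= 30

    def test_class_imbalance_near_target(self):
        """Dataset-level mitotic fraction lands within 5 percentage points
        of the configured target across 100 images."""
        cfg = SynthConfig(n_images=100, image_size=256,
                          mitotic_fraction=0.08, seed=21)
        ds = generate_synthetic_dataset(cfg)
        nm = sum(1 for bs in ds.annotations for _, c in bs if c == 0)
        nh = sum(1 for bs in ds.annotations for _, c in bs if c == 1)
        frac = nm / (nm + nh)
        assert abs(frac - 0.08) < 0.05
        assert frac < 0.10                      # mitoses stay the minority

    def test_boxes_tight_around_blobs(self):
        """Each annotated box matches the bounding box of the dark blob
        recovered from the rendered image (IoU >= 0.9), at the generator's
        standard blob scale."""
        cfg = SynthConfig(n_images=1, image_size=256, seed=4)
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(6):
            img, boxes = generate_synthetic_image(rng, cfg)
            lum = img.astype(float).mean(axis=2)
            bg = np.median(lum)
            for (x0, y0, x1, y1), _ in boxes:
                pad = 3
                xa, ya = max(int(x0) - pad, 0), max(int(y0) - pad, 0)
                xb = min(int(np.ceil(x1)) + pad, 256)
                yb = min(int(np.ceil(y1)) + pad, 256)
                sub = lum[ya:yb, xa:xb]
                mask = sub < bg - 0.55 * (bg - sub.min())
                lab, n = ndimage.label(mask)
                assert n >= 1
                bx0, by0 = int(x0) - xa, int(y0) - ya
                bx1 = int(np.ceil(x1)) - xa
                by1 = int(np.ceil(y1)) - ya
                keep = np.zeros(n + 1, bool)
                for comp in range(1, n + 1):
                    cys, cxs = np.nonzero(lab == comp)
                    inside = ((cys >= by0) & (cys < by1) &
                              (cxs >= bx0) & (cxs < bx1)).sum()
                    keep[comp] = inside >= 0.5 * cys.size
                ys, xs = np.nonzero(keep[lab])
                assert ys.size
                m = (xa + xs.min(), ya + ys.min(),
                     xa + xs.max() + 1, ya + ys.max() + 1)
                ix0, iy0 = max(x0, m[0]), max(y0, m[1])
                ix1, iy1 = min(x1, m[2]), min(y1, m[3])
                inter = max(ix1 - ix0, 0) * max(iy1 - iy0, 0)
                union = ((x1 - x0) * (y1 - y0)
                         + (m[2] - m[0]) * (m[3] - m[1]) - inter)
                assert inter / union >= 0.9
                checked += 1
        assert checked > 20

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(mitotic_fraction=1.5)
        with pytest.raises(ValueError):
            SynthConfig(mitoses_per_image=(5, 2))

    def test_written_dataset_round_trips(self, tmp_path):
        from iihgnn.data.dataset import load_dataset_dir
        cfg = SynthConfig.smoke(n_images=4, seed=8)
        ds = generate_synthetic_dataset(cfg, out_dir=tmp_path)
        back = load_dataset_dir(tmp_path)
        assert len(back) == 4
        assert set(back.splits) == {"train", "val", "test"}
        for a, b in zip(ds.images, back.images):
            assert np.array_equal(a, b)
        for anns_a, anns_b in zip(ds.annotations, back.annotations):
            assert len(anns_a) == len(anns_b)
            for (ba, ca), (bb, cb) in zip(anns_a, anns_b):
                assert ca == cb and np.allclose(ba, bb, atol=1e-4)
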