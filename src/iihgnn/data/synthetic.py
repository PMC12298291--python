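"""Seeded generator of MIDOG-like synthetic histology patches.

Real mitosis-detection data consists of H&E-stained tissue patches in
which mitotic figures appear as small, dark, basophilic (blue-purple)
structures — often elongated or bi-lobed during metaphase/anaphase — that
are easily confused with apoptotic cells and other dark round nuclei, and
form a small minority of all annotated cells. The generator emulates that
regime on a textured pink background:

* **mitotic figures** (class 0): dark, eccentric ellipses, usually with a
  second offset lobe (a chromosome-plate caricature);
* **hard negatives** (class 1): similarly dark, rounder single blobs whose
  darkness range overlaps the mitotic range across images;
* unlabeled round nuclei of intermediate tone as background clutter.

Each image also carries a global stain/intensity factor emulating
scanner-to-scanner staining variability: the absolute darkness of a blob
is ambiguous across images, while the relative contrast between mitoses
and their neighbours within an image stays informative — the cue a
pathologist (and a context-aware model) actually uses.

Per-image hard-negative counts are derived from the mitosis count so the
dataset-level mitotic fraction — mitoses / (mitoses + hard negatives) —
approaches the configured target (default 0.08, i.e. mitoses are well
under 10 % of annotated objects). A single seed fully determines every
image and annotation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SynthConfig", "SyntheticDataset", "generate_synthetic_dataset"]

# H&E-like palette (RGB in [0,1])
_BACKGROUND = np.array([0.87, 0.73, 0.83])
_MITOTIC_COLOR = np.array([0.16, 0.09, 0.34])
_HARDNEG_COLOR = np.array([0.24, 0.15, 0.42])
_NUCLEUS_COLOR = np.array([0.45, 0.32, 0.60])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic patch generator."""
    n_images: int = 100
    image_size: int = 640
    mitoses_per_image: tuple = (1, 3)
    hard_negatives_per_image: tuple = (4, 40)
    mitotic_fraction: float = 0.08
    blob_radius: tuple = (6, 14)           # semi-major axis range, px
    mitotic_eccentricity: tuple = (1.4, 2.6)   # major/minor axis ratio
    hardneg_eccentricity: tuple = (1.0, 1.6)
    lobe_probability: float = 0.6          # chance a mitosis shows a 2nd lobe
    intensity_jitter: float = 0.12         # per-blob darkness jitter
    stain_jitter: float = 0.35             # per-image staining variability
    n_background_nuclei: tuple = (0, 0)    # unlabeled clutter, per image
    texture_sigma: float = 3.0             # background texture scale, px
    texture_amplitude: float = 0.045
    noise_amplitude: float = 0.015         # per-pixel sensor-like noise
    label_hard_negatives: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.mitotic_fraction < 1.0):
            raise ValueError("mitotic_fraction must be in (0, 1)")
        for name in ("mitoses_per_image", "hard_negatives_per_image",
                     "blob_radius", "n_background_nuclei"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_images < 1 or self.image_size < 32:
            raise ValueError("need n_images >= 1 and image_size >= 32")
        if self.blob_radius[1] * 4 > self.image_size:
            raise ValueError("blob_radius too large for image_size")

    @classmethod
    def smoke(cls, n_images=200, seed=0):
        """Scaled-down conditions for desk-scale training: 128-px patches
        with proportionally fewer objects; mitoses remain the minority
        class (target fraction 0.25 of annotated objects)."""
        return cls(n_images=n_images, image_size=128,
                   mitoses_per_image=(1, 3), hard_negatives_per_image=(2, 12),
                   mitotic_fraction=0.25, blob_radius=(4, 8),
                   n_background_nuclei=(2, 5), seed=seed)


@dataclass
class SyntheticDataset:
    images: list                       # uint8 (H, W, 3) arrays
    annotations: list                  # per image: [((x0,y0,x1,y1), cls), ...]
    config: SynthConfig
    splits: dict = field(default_factory=dict)   # name -> list of indices

    def __len__(self):
        return len(self.images)


def _ellipse_mask(shape, cy, cx, a, b, angle):
    """Soft [0,1] mask of a rotated ellipse (a = semi-major, b = semi-minor)."""
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    dy, dx = y - cy, x - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = (r2 <= 1.0).astype(float)
    return gaussian_filter(mask, 0.8)


def _ellipse_bbox(cy, cx, a, b, angle):
    """Tight axis-aligned bbox of a rotated ellipse (closed form)."""
    ca, sa = np.cos(angle), np.sin(angle)
    ex = np.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    ey = np.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    return (cx - ex, cy - ey, cx + ex, cy + ey)


def _merge_boxes(b1, b2):
    return (min(b1[0], b2[0]), min(b1[1], b2[1]),
            max(b1[2], b2[2]), max(b1[3], b2[3]))


def _place_centers(rng, n, size, margin, min_dist, existing):
    """Rejection-sample n blob centers keeping a minimum separation."""
    centers = []
    for _ in range(n):
        for _attempt in range(50):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist ** 2
                   for y, x in existing + centers):
                centers.append((cy, cx))
                break
    return centers


def _render_blob(img, rng, cfg, cy, cx, kind, stain=1.0):
    """Draw one object; returns (tight bbox, blob mask).

    `stain` is the image-wide intensity factor: it scales every blob in an
    image, so absolute darkness is uninformative across images while
    within-image contrast between kinds is preserved."""
    size = cfg.image_size
    a = rng.uniform(*cfg.blob_radius)
    if kind == "mitotic":
        ecc = rng.uniform(*cfg.mitotic_eccentricity)
        color = _MITOTIC_COLOR
    elif kind == "hardneg":
        ecc = rng.uniform(*cfg.hardneg_eccentricity)
        color = _HARDNEG_COLOR
    else:
        ecc = rng.uniform(1.0, 1.2)
        color = _NUCLEUS_COLOR
        a *= 0.8
    b = a / ecc
    angle = rng.uniform(0, np.pi)
    mask = _ellipse_mask((size, size), cy, cx, a, b, angle)
    bbox = _ellipse_bbox(cy, cx, a, b, angle)
    if kind == "mitotic" and rng.random() < cfg.lobe_probability:
        # second lobe along the major axis: chromosome-plate caricature
        off = rng.uniform(0.5, 0.9) * a
        ly = cy + off * np.sin(angle)
        lx = cx + off * np.cos(angle)
        la, lb = 0.55 * a, 0.55 * b
        lobe = _ellipse_mask((size, size), ly, lx, la, lb, angle)
        mask = np.maximum(mask, lobe)
        bbox = _merge_boxes(bbox, _ellipse_bbox(ly, lx, la, lb, angle))
    jitter = 1.0 + rng.uniform(-cfg.intensity_jitter, cfg.intensity_jitter)
    col = np.clip(color * jitter * stain, 0, 1)
    alpha = np.clip(mask, 0, 1)[..., None]
    img *= (1 - 0.95 * alpha)
    img += 0.95 * alpha * col
    # ground-truth box from the rendered mask's half-intensity contour:
    # tight around what is actually visible, robust to edge blur
    ys, xs = np.nonzero(mask >= 0.5)
    if ys.size:
        bbox = (float(xs.min()), float(ys.min()),
                float(xs.max() + 1), float(ys.max() + 1))
    else:
        x0, y0, x1, y1 = bbox
        bbox = (max(x0, 0.0), max(y0, 0.0), min(x1, size), min(y1, size))
    return bbox, mask


def _derive_counts(rng, cfg):
    lo, hi = cfg.mitoses_per_image
    n_mit = int(rng.integers(lo, hi + 1))
    f = cfg.mitotic_fraction
    target_hn = n_mit * (1.0 - f) / f
    jitter = rng.integers(-1, 2)
    hlo, hhi = cfg.hard_negatives_per_image
    n_hn = int(np.clip(round(target_hn) + jitter, hlo, hhi))
    return n_mit, n_hn


def generate_synthetic_image(rng, cfg: SynthConfig):
    """One textured patch with annotated mitotic/hard-negative blobs.

    Returns (uint8 image, [((x0,y0,x1,y1), class_id), ...]).
    """
    size = cfg.image_size
    stain = rng.uniform(1.0 - cfg.stain_jitter, 1.0 + cfg.stain_jitter)
    img = np.empty((size, size, 3))
    img[:] = np.clip(_BACKGROUND * (0.85 + 0.15 * stain), 0, 1)
    tex = gaussian_filter(rng.normal(size=(size, size)), cfg.texture_sigma)
    tex /= max(np.abs(tex).max(), 1e-9)
    img += cfg.texture_amplitude * tex[..., None]

    n_mit, n_hn = _derive_counts(rng, cfg)
    n_bg = int(rng.integers(cfg.n_background_nuclei[0],
                            cfg.n_background_nuclei[1] + 1))
    margin = cfg.blob_radius[1] * 1.8
    min_dist = cfg.blob_radius[1] * 2.2
    placed = []
    boxes = []
    for kind, count in (("mitotic", n_mit), ("hardneg", n_hn),
                        ("nucleus", n_bg)):
        centers = _place_centers(rng, count, size, margin, min_dist, placed)
        placed.extend(centers)
        for cy, cx in centers:
            bbox, _ = _render_blob(img, rng, cfg, cy, cx, kind, stain=stain)
            if kind == "mitotic":
                boxes.append((bbox, 0))
            elif kind == "hardneg" and cfg.label_hard_negatives:
                boxes.append((bbox, 1))
    img += cfg.noise_amplitude * rng.normal(size=img.shape)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), boxes


def _split_indices(n, rng):
    """70/15/15 image-level split, mirroring slide-level leakage control."""
    idx = rng.permutation(n)
    n_tr = int(round(0.7 * n))
    n_va = int(round(0.15 * n))
    return {"train": sorted(int(i) for i in idx[:n_tr]),
            "val": sorted(int(i) for i in idx[n_tr:n_tr + n_va]),
            "test": sorted(int(i) for i in idx[n_tr + n_va:])}


def generate_synthetic_dataset(cfg: SynthConfig,
                               out_dir=None) -> SyntheticDataset:
    """Generate `cfg.n_images` patches; optionally write them to `out_dir`
    (PNG images, YOLO-txt labels, a COCO JSON and a manifest YAML)."""
    rng = np.random.default_rng(cfg.seed)
    images, annotations = [], []
    for _ in range(cfg.n_images):
        img, boxes = generate_synthetic_image(rng, cfg)
        images.append(img)
        annotations.append(boxes)
    splits = _split_indices(cfg.n_images, rng)
    ds = SyntheticDataset(images=images, annotations=annotations,
                          config=cfg, splits=splits)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out: Path):
    import json

    import yaml
    from PIL import Image

    from .annotations import write_annotations

    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    size = ds.config.image_size
    coco = {"images": [], "annotations": [], "categories": [
        {"id": 0, "name": "mitotic_figure"},
        {"id": 1, "name": "hard_negative"}]}
    aid = 1
    for i, (img, boxes) in enumerate(zip(ds.images, ds.annotations)):
        name = f"patch_{i:05d}.png"
        Image.fromarray(img).save(out / "images" / name)
        write_annotations(boxes, out / "labels" / f"patch_{i:05d}.txt",
                          "yolo", image_size=(size, size))
        coco["images"].append({"id": i + 1, "file_name": name,
                               "width": size, "height": size})
        for (x0, y0, x1, y1), c in boxes:
            coco["annotations"].append(
                {"id": aid, "image_id": i + 1, "category_id": int(c),
                 "bbox": [x0, y0, x1 - x0, y1 - y0],
                 "area": (x1 - x0) * (y1 - y0), "iscrowd": 0})
            aid += 1
    (out / "annotations.json").write_text(json.dumps(coco))
    manifest = {"n_images": ds.config.n_images, "image_size": size,
                "seed": ds.config.seed,
                "splits": {k: [f"patch_{i:05d}.png" for i in v]
                           for k, v in ds.splits.items()}}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
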