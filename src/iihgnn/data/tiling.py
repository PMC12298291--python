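"""Whole-slide-style tiling with bounding-box remapping.

Large images are cut into fixed-size patches on a row-major grid (default
stride = patch size, i.e. no overlap; the final row/column is anchored to
the image edge so the union of tiles always covers the full extent).
Every annotation is duplicated into each patch it intersects, translated
into patch-local coordinates and clipped to the patch; a clipped box whose
area falls below ``min_visibility`` of the original area is dropped for
that patch. Boxes that survive in no patch at all are reported — nothing
is lost silently.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class AnnotatedPatch:
    """An image tile plus its remapped (patch-local) box labels."""
    image: np.ndarray
    boxes: list                      # [((x0, y0, x1, y1), class_id), ...]
    origin: tuple                    # (row_offset, col_offset) in the source

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for (x0, y0, x1, y1), _ in self.boxes:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"box {(x0, y0, x1, y1)} outside "
                                 f"{w}x{h} patch")


@dataclass
class PatchingResult:
    patches: list
    n_source_boxes: int
    dropped: list = field(default_factory=list)  # indices of lost boxes

    @property
    def n_dropped(self):
        return len(self.dropped)


def _tile_starts(extent: int, size: int, stride: int):
    starts = list(range(0, extent - size + 1, stride))
    if not starts or starts[-1] != extent - size:
        starts.append(extent - size)
    return starts


def patch_wsi(image, annotations, patch_size=640, stride=None,
              min_visibility=0.4) -> PatchingResult:
    """Tile `image` into patch_size x patch_size patches and remap boxes.

    Parameters
    ----------
    image : (H, W[, C]) array
    annotations : list of ((x0, y0, x1, y1), class_id) in source pixels
    stride : tile step, default = patch_size (no overlap)
    min_visibility : minimum clipped/original area fraction to keep a box
        in a patch (boundary-straddling boxes are clipped, not shifted)
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    H, W = image.shape[:2]
    if patch_size > H or patch_size > W:
        raise ValueError(f"patch_size {patch_size} exceeds image {W}x{H}")
    stride = patch_size if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be >= 1")

    kept_somewhere = np.zeros(len(annotations), dtype=bool)
    patches = []
    for r0 in _tile_starts(H, patch_size, stride):
        for c0 in _tile_starts(W, patch_size, stride):
            tile = image[r0:r0 + patch_size, c0:c0 + patch_size]
            boxes = []
            for i, ((x0, y0, x1, y1), cls) in enumerate(annotations):
                cx0 = max(x0, c0)
                cy0 = max(y0, r0)
                cx1 = min(x1, c0 + patch_size)
                cy1 = min(y1, r0 + patch_size)
                if cx1 <= cx0 or cy1 <= cy0:
                    continue
                area = (x1 - x0) * (y1 - y0)
                if area <= 0:
                    continue
                if (cx1 - cx0) * (cy1 - cy0) / area < min_visibility:
                    continue
                boxes.append(((cx0 - c0, cy0 - r0, cx1 - c0, cy1 - r0), cls))
                kept_somewhere[i] = True
            patches.append(AnnotatedPatch(image=tile, boxes=boxes,
                                          origin=(r0, c0)))
    dropped = [int(i) for i in np.flatnonzero(~kept_somewhere)]
    if dropped:
        log.info("patch_wsi: %d/%d boxes dropped by the visibility rule",
                 len(dropped), len(annotations))
    return PatchingResult(patches=patches, n_source_boxes=len(annotations),
                          dropped=dropped)
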