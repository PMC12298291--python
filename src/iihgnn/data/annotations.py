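"""Bounding-box annotation I/O: COCO JSON and YOLO-txt.

Internally a box is always ``(x_min, y_min, x_max, y_max)`` in 0-based,
half-open pixel coordinates, paired with an integer class id. Conversions
to the on-disk conventions (COCO: absolute ``[x, y, w, h]``; YOLO: one
``class cx cy w h`` line per object, normalised to [0, 1]) happen only at
the format boundary and round-trip losslessly up to float precision.
"""
from __future__ import annotations

import json
from pathlib import Path


class AnnotationFormatError(ValueError):
    """Raised on malformed annotation files; names the offending record."""


def boxes_yolo_to_coco(rows, image_size):
    """(class, cx, cy, w, h) normalised -> list of ((x0,y0,x1,y1), class)."""
    W, H = image_size
    out = []
    for cls, cx, cy, w, h in rows:
        bw, bh = w * W, h * H
        x0, y0 = cx * W - bw / 2, cy * H - bh / 2
        out.append(((x0, y0, x0 + bw, y0 + bh), int(cls)))
    return out


def boxes_coco_to_yolo(boxes, image_size):
    """list of ((x0,y0,x1,y1), class) -> (class, cx, cy, w, h) normalised."""
    W, H = image_size
    rows = []
    for (x0, y0, x1, y1), cls in boxes:
        rows.append((int(cls), (x0 + x1) / 2 / W, (y0 + y1) / 2 / H,
                     (x1 - x0) / W, (y1 - y0) / H))
    return rows


def _read_yolo(path, image_size):
    if image_size is None:
        raise ValueError("YOLO-txt I/O needs image_size=(W, H)")
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationFormatError(
                f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as e:
            raise AnnotationFormatError(f"{path}:{lineno}: {e}") from None
        rows.append((cls, *vals))
    return boxes_yolo_to_coco(rows, image_size)


def _write_yolo(boxes, path, image_size):
    if image_size is None:
        raise ValueError("YOLO-txt I/O needs image_size=(W, H)")
    lines = [f"{c} {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}"
             for c, cx, cy, w, h in boxes_coco_to_yolo(boxes, image_size)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_coco(path):
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationFormatError(f"{path}: invalid JSON ({e})") from None
    boxes = []
    for i, ann in enumerate(doc.get("annotations", [])):
        try:
            x, y, w, h = ann["bbox"]
            cls = int(ann["category_id"])
        except (KeyError, TypeError, ValueError) as e:
            raise AnnotationFormatError(
                f"{path}: annotation record {i}: {e}") from None
        boxes.append(((float(x), float(y), float(x) + float(w),
                       float(y) + float(h)), cls))
    return boxes


def _write_coco(boxes, path, image_size=None, image_name="image.png",
                categories=None):
    W, H = image_size if image_size is not None else (None, None)
    if categories is None:
        cids = sorted({c for _, c in boxes}) or [0]
        categories = [{"id": c, "name": f"class_{c}"} for c in cids]
    doc = {
        "images": [{"id": 1, "file_name": image_name,
                    "width": W, "height": H}],
        "annotations": [
            {"id": i + 1, "image_id": 1, "category_id": int(c),
             "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
             "area": float((x1 - x0) * (y1 - y0)), "iscrowd": 0}
            for i, ((x0, y0, x1, y1), c) in enumerate(boxes)],
        "categories": categories,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations(path, format, image_size=None):
    """Read boxes from `path`; format is 'coco' or 'yolo'."""
    if format == "coco":
        return _read_coco(path)
    if format == "yolo":
        return _read_yolo(path, image_size)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotations(boxes, path, format, image_size=None, **kw):
    """Write boxes to `path`; format is 'coco' or 'yolo'."""
    if format == "coco":
        return _write_coco(boxes, path, image_size=image_size, **kw)
    if format == "yolo":
        return _write_yolo(boxes, path, image_size)
    raise ValueError(f"unknown annotation format {format!r}")
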