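"""Load a dataset directory (images/ + labels/ YOLO-txt + manifest.yaml)."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .annotations import read_annotations


@dataclass
class LoadedDataset:
    images: list
    annotations: list
    names: list = field(default_factory=list)
    splits: dict = field(default_factory=dict)

    def subset(self, split: str) -> "LoadedDataset":
        if split not in self.splits:
            raise KeyError(f"no split {split!r}; have {list(self.splits)}")
        name_to_idx = {n: i for i, n in enumerate(self.names)}
        idx = [name_to_idx[n] for n in self.splits[split]]
        return LoadedDataset(images=[self.images[i] for i in idx],
                             annotations=[self.annotations[i] for i in idx],
                             names=[self.names[i] for i in idx])

    def __len__(self):
        return len(self.images)


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def load_dataset_dir(root) -> LoadedDataset:
    root = Path(root)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {root}")
    images, annotations, names = [], [], []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif",
                                           ".tiff"):
            continue
        img = load_image(img_path)
        h, w = img.shape[:2]
        label = root / "labels" / (img_path.stem + ".txt")
        boxes = (read_annotations(label, "yolo", image_size=(w, h))
                 if label.exists() else [])
        images.append(img)
        annotations.append(boxes)
        names.append(img_path.name)
    splits = {}
    manifest = root / "manifest.yaml"
    if manifest.exists():
        doc = yaml.safe_load(manifest.read_text()) or {}
        splits = doc.get("splits", {})
    return LoadedDataset(images=images, annotations=annotations,
                         names=names, splits=splits)
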