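"""Generate a seeded synthetic histology-patch dataset and inspect it.

The generator emulates the data regime of mitosis detection: dark
two-lobed mitotic figures are a small minority among visually similar
hard negatives, and each image carries its own staining intensity.
"""
import numpy as np

from iihgnn import SynthConfig, generate_synthetic_dataset

cfg = SynthConfig(n_images=30, image_size=256, seed=7)
ds = generate_synthetic_dataset(cfg)

n_mit = sum(1 for boxes in ds.annotations for _, c in boxes if c == 0)
n_hn = sum(1 for boxes in ds.annotations for _, c in boxes if c == 1)
print(f"images: {len(ds)}  mitoses: {n_mit}  hard negatives: {n_hn}")
print(f"mitotic fraction: {n_mit / (n_mit + n_hn):.3f} "
      f"(target {cfg.mitotic_fraction})")
sizes = [max(x1 - x0, y1 - y0)
         for boxes in ds.annotations for (x0, y0, x1, y1), _ in boxes]
print(f"object sizes: {min(sizes):.0f}-{max(sizes):.0f} px "
      f"(median {np.median(sizes):.0f})")
print(f"splits: { {k: len(v) for k, v in ds.splits.items()} }")
# The fraction says mitoses are rare, as in real slides; sizes confirm the
# objects are small relative to the 256-px patch.
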