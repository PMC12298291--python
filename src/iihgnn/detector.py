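"""Single-stage mitosis detector: BBMM backbone, hypergraph neck,
bottom-up fusion and an anchor-free YOLO-style head.

The backbone downsamples an RGB patch through five strided stages; the
three deepest stages (strides 8/16/32) feed the head, and a five-map
pyramid (padded with pooled copies of the deepest stage unless the
``five_stage`` config adds real P6/P7 stages) feeds the hypergraph neck.
The neck's grid output is redistributed to the three head scales and
added to the backbone maps; a bottom-up path then pushes the fused
high-resolution maps down the scale hierarchy so fine spatial detail
survives to the coarser scales. Each head cell predicts a box
(center offsets through a sigmoid, log-scale width/height), an
objectness logit and per-class logits.

During training the objectness target of an assigned cell is the IoU of
its decoded box with the ground truth, so the learned confidence
approximates Pr(object) x IoU; at inference the reported confidence is
sigmoid(objectness) x sigmoid(class score), as the true IoU is
unobservable.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import (Adam, Tensor, avg_pool2d, bce_with_logits, concat,
                       exp, maximum, minimum, sigmoid)
from .blocks import BBMM, BBMMConfig, C3K2Block
from .hypergraph import DEFAULT_LAMBDA, HypergraphNeck
from .layers import Conv2d, ConvBNAct, Module, DTYPE

__all__ = ["ModelConfig", "Detection", "MitosisDetector", "confidence_score",
           "decode_and_nms", "nms", "train_loop", "TrainResult",
           "save_checkpoint", "load_checkpoint", "evaluate_model"]

STRIDES = (8, 16, 32)


@dataclass
class ModelConfig:
    """Everything needed to build and run the detector."""
    input_size: int = 640
    n_classes: int = 2                      # mitotic figure, hard negative
    widths: tuple = (16, 32, 48, 64, 80)    # stem, s4, P3, P4, P5 channels
    n_bottlenecks: int = 1
    use_bbmm: bool = True
    bbmm_stages: tuple = ("P2", "P3", "P4", "P5")  # which blocks are BBMM
    bbmm_fusion: str = "concat+project"
    bbmm_kernel: int = 3
    use_hgnn: bool = True
    lambda_thresh: float = DEFAULT_LAMBDA
    hgnn_layers: int = 1
    common_grid: object = "middle"          # "middle" or (H, W)
    five_stage: bool = False                # real P6/P7 stages vs pooled pads
    conf_thresh: float = 0.25
    nms_iou: float = 0.45
    max_detections: int = 300
    lr: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if len(self.widths) != 5:
            raise ValueError("widths must give 5 stage channel counts")

    @classmethod
    def reduced(cls, **kw):
        """Width-reduced configuration for CPU-scale experiments on
        128-px patches."""
        defaults = dict(input_size=128, widths=(8, 16, 24, 32, 40),
                        common_grid=(8, 8), lr=5e-3,
                        bbmm_stages=("P3", "P4", "P5"))
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class Detection:
    """One detected object: xyxy pixel box, class id, confidence."""
    box: tuple
    class_id: int
    confidence: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def confidence_score(pr_object: float, iou: float) -> float:
    """Detection confidence = Pr(object) x IoU(pred, truth)."""
    if not (0.0 <= pr_object <= 1.0 and 0.0 <= iou <= 1.0):
        raise ValueError("confidence_score inputs must lie in [0, 1]")
    return pr_object * iou


class MitosisDetector(Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        w0, w1, c3, c4, c5 = cfg.widths

        def block(ci, co, stage):
            if cfg.use_bbmm and stage in cfg.bbmm_stages:
                return BBMM(rng, BBMMConfig(ci, co,
                                            branch_fusion=cfg.bbmm_fusion,
                                            n_bottlenecks=cfg.n_bottlenecks,
                                            kernel=cfg.bbmm_kernel))
            return C3K2Block(rng, ci, co, n=cfg.n_bottlenecks)

        self.stem = ConvBNAct(rng, 3, w0, k=3, stride=2)
        self.down1 = ConvBNAct(rng, w0, w1, k=3, stride=2)
        self.block1 = block(w1, w1, "P2")
        self.down2 = ConvBNAct(rng, w1, c3, k=3, stride=2)
        self.block2 = block(c3, c3, "P3")
        self.down3 = ConvBNAct(rng, c3, c4, k=3, stride=2)
        self.block3 = block(c4, c4, "P4")
        self.down4 = ConvBNAct(rng, c4, c5, k=3, stride=2)
        self.block4 = block(c5, c5, "P5")
        if cfg.five_stage:
            self.down5 = ConvBNAct(rng, c5, c5, k=3, stride=2)
            self.down6 = ConvBNAct(rng, c5, c5, k=3, stride=2)
        stage_channels = (c3, c4, c5, c5, c5)
        self.neck = HypergraphNeck(rng, stage_channels, (c3, c4, c5),
                                   lambda_thresh=cfg.lambda_thresh,
                                   n_layers=cfg.hgnn_layers,
                                   common_grid=cfg.common_grid)
        # bottom-up path: push fused shallow detail down the scales
        self.bu1 = ConvBNAct(rng, c3, c4, k=3, stride=2)
        self.bu2 = ConvBNAct(rng, c4, c5, k=3, stride=2)
        self.heads = []
        for c in (c3, c4, c5):
            trunk = ConvBNAct(rng, c, c, k=3)
            out = Conv2d(rng, c, 5 + cfg.n_classes, k=1)
            # bias priors: rare objectness, weak class logits
            out.bias.data[4] = -4.0
            out.bias.data[5:] = -2.0
            self.heads.append((trunk, out))
        self.head_mods = [m for pair in self.heads for m in pair]

    # -- forward ------------------------------------------------------------
    def backbone(self, x: Tensor):
        x = self.stem(x)
        x = self.block1(self.down1(x))
        p3 = self.block2(self.down2(x))
        p4 = self.block3(self.down3(p3))
        p5 = self.block4(self.down4(p4))
        if self.cfg.five_stage:
            p6 = self.down5(p5)
            p7 = self.down6(p6)
        else:
            p6 = avg_pool2d(p5, 2) if p5.shape[-1] >= 2 else p5
            p7 = avg_pool2d(p6, 2) if p6.shape[-1] >= 2 else p6
        return [p3, p4, p5, p6, p7]

    def forward(self, x: Tensor):
        """x: (B, 3, S, S) in [0, 1] -> list of 3 raw per-scale maps
        (B, 5 + n_classes, S/stride, S/stride)."""
        if x.shape[-1] != self.cfg.input_size or \
                x.shape[-2] != self.cfg.input_size:
            raise ValueError(f"expected {self.cfg.input_size}-px input, "
                             f"got {x.shape[-2:]}")
        pyramid = self.backbone(x)
        head_maps = pyramid[:3]
        if self.cfg.use_hgnn:
            neck_maps = self.neck(pyramid)
            fused = self.bottom_up_fuse(neck_maps, head_maps)
        else:
            fused = self.bottom_up_fuse(None, head_maps)
        outs = []
        for (trunk, out), f in zip(self.heads, fused):
            outs.append(out(trunk(f)))
        return outs

    def bottom_up_fuse(self, neck_maps, backbone_maps):
        """Add the hypergraph neck output to the last three backbone maps,
        then propagate the shallow fused map downward (stride-2 convs) so
        high-resolution detail reaches the deeper scales."""
        if neck_maps is None:
            f3, f4, f5 = backbone_maps
        else:
            if len(neck_maps) != 3 or len(backbone_maps) != 3:
                raise ValueError("bottom-up fusion expects 3 scales")
            for n, b in zip(neck_maps, backbone_maps):
                if n.shape != b.shape:
                    raise ValueError(f"scale mismatch {n.shape} vs {b.shape}")
            f3, f4, f5 = (n + b for n, b in zip(neck_maps, backbone_maps))
        f4 = f4 + self.bu1(f3)
        f5 = f5 + self.bu2(f4)
        return [f3, f4, f5]


# --------------------------------------------------------------------------
# decoding and NMS
# --------------------------------------------------------------------------

def _sigmoid_np(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _decode_scale(raw: np.ndarray, stride: int, n_classes: int):
    """raw (5+nc, H, W) -> boxes (N,4), obj (N,), cls_scores (N, nc)."""
    _, H, W = raw.shape
    gi, gj = np.mgrid[0:H, 0:W]
    s = _sigmoid_np(raw[:2])
    cx = (gj + s[0]) * stride
    cy = (gi + s[1]) * stride
    bw = np.exp(np.clip(raw[2], -8, 8)) * stride
    bh = np.exp(np.clip(raw[3], -8, 8)) * stride
    boxes = np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2],
                     axis=-1).reshape(-1, 4)
    obj = _sigmoid_np(raw[4]).reshape(-1)
    cls = _sigmoid_np(raw[5:]).reshape(raw.shape[0] - 5, -1).T
    return boxes, obj, cls


def nms(boxes, scores, iou_thresh):
    """Greedy non-maximum suppression; returns kept indices, sorted by
    descending score."""
    from .metrics import box_iou
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep = []
    suppressed = np.zeros(len(order), dtype=bool)
    boxes = np.asarray(boxes, dtype=float)
    for ii, i in enumerate(order):
        if suppressed[ii]:
            continue
        keep.append(int(i))
        rest = order[ii + 1:]
        if rest.size:
            ious = box_iou(boxes[i:i + 1], boxes[rest])[0]
            suppressed[ii + 1:] |= ious > iou_thresh
    return keep


def decode_and_nms(raw_maps, cfg: ModelConfig, image_index=0):
    """Raw per-scale maps -> list of Detection for one image, sorted by
    descending confidence."""
    if not (0 < cfg.conf_thresh <= 1 and 0 < cfg.nms_iou < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    all_boxes, all_conf, all_cls = [], [], []
    for raw, stride in zip(raw_maps, STRIDES):
        data = raw.data if isinstance(raw, Tensor) else raw
        boxes, obj, cls = _decode_scale(np.asarray(data[image_index]),
                                        stride, cfg.n_classes)
        conf = obj[:, None] * cls                     # (N, nc)
        best = conf.argmax(axis=1)
        best_conf = conf[np.arange(len(best)), best]
        m = best_conf >= cfg.conf_thresh
        all_boxes.append(boxes[m])
        all_conf.append(best_conf[m])
        all_cls.append(best[m])
    boxes = np.concatenate(all_boxes)
    confs = np.concatenate(all_conf)
    clss = np.concatenate(all_cls)
    dets = []
    for c in np.unique(clss):
        idx = np.flatnonzero(clss == c)
        keep = nms(boxes[idx], confs[idx], cfg.nms_iou)
        for k in keep:
            i = idx[k]
            x0, y0, x1, y1 = boxes[i]
            if x1 <= x0 or y1 <= y0:
                continue
            dets.append(Detection(box=(float(x0), float(y0), float(x1),
                                       float(y1)),
                                  class_id=int(c),
                                  confidence=float(min(confs[i], 1.0))))
    dets.sort(key=lambda d: -d.confidence)
    return dets[: cfg.max_detections]


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def _assign_targets(annotations, cfg: ModelConfig, shapes):
    """Center-cell assignment: each ground truth goes to the scale whose
    stride best matches its size, at the cell containing its center."""
    per_scale = [[] for _ in STRIDES]
    for b, boxes in enumerate(annotations):
        for (x0, y0, x1, y1), cls in boxes:
            w, h = x1 - x0, y1 - y0
            si = int(np.argmin([abs(np.log(max(w, h) / (3.0 * s)))
                                for s in STRIDES]))
            s = STRIDES[si]
            Hs, Ws = shapes[si]
            j = min(int((x0 + x1) / 2 / s), Ws - 1)
            i = min(int((y0 + y1) / 2 / s), Hs - 1)
            per_scale[si].append((b, i, j, (x0, y0, x1, y1), int(cls)))
    return per_scale


def compute_loss(raw_maps, annotations, cfg: ModelConfig):
    """Composite detection loss: IoU box loss + objectness BCE (target =
    decoded-box IoU at assigned cells) + class BCE. Returns (loss Tensor,
    dict of floats)."""
    shapes = [r.shape[-2:] for r in raw_maps]
    per_scale = _assign_targets(annotations, cfg, shapes)
    B = raw_maps[0].shape[0]
    n_pos = sum(len(p) for p in per_scale)
    box_loss = Tensor(np.zeros((), DTYPE))
    cls_loss = Tensor(np.zeros((), DTYPE))
    obj_loss = Tensor(np.zeros((), DTYPE))
    for raw, stride, pos in zip(raw_maps, STRIDES, per_scale):
        Hs, Ws = raw.shape[-2:]
        t_obj = np.zeros((B, Hs, Ws), dtype=DTYPE)
        w_obj = np.full((B, Hs, Ws), 0.15, dtype=DTYPE)
        if pos:
            bs = np.array([p[0] for p in pos])
            is_ = np.array([p[1] for p in pos])
            js = np.array([p[2] for p in pos])
            gt = np.array([p[3] for p in pos], dtype=DTYPE)
            cls_ids = np.array([p[4] for p in pos])
            pred = raw[bs, :, is_, js]                 # (k, 5+nc)
            sx = sigmoid(pred[:, 0])
            sy = sigmoid(pred[:, 1])
            cx = (sx + js.astype(DTYPE)) * stride
            cy = (sy + is_.astype(DTYPE)) * stride
            bw = exp(pred[:, 2].clip(-8, 8)) * stride
            bh = exp(pred[:, 3].clip(-8, 8)) * stride
            px0, px1 = cx - bw * 0.5, cx + bw * 0.5
            py0, py1 = cy - bh * 0.5, cy + bh * 0.5
            ix0 = maximum(px0, gt[:, 0])
            iy0 = maximum(py0, gt[:, 1])
            ix1 = minimum(px1, gt[:, 2])
            iy1 = minimum(py1, gt[:, 3])
            iw = maximum(ix1 - ix0, 0.0)
            ih = maximum(iy1 - iy0, 0.0)
            inter = iw * ih
            area_p = bw * bh
            area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
            iou = inter / (area_p + Tensor(area_g) - inter + 1e-9)
            box_loss = box_loss + (1.0 - iou).sum()
            t_obj[bs, is_, js] = np.clip(iou.data, 0, 1)   # detached target
            w_obj[bs, is_, js] = 2.0
            t_cls = np.zeros((len(pos), cfg.n_classes), dtype=DTYPE)
            t_cls[np.arange(len(pos)), cls_ids] = 1.0
            cls_loss = cls_loss + bce_with_logits(pred[:, 5:], t_cls)
        obj_loss = obj_loss + bce_with_logits(raw[:, 4], t_obj, weight=w_obj)
    denom = max(n_pos, 1)
    total = (5.0 * box_loss + obj_loss + cls_loss) * (1.0 / denom)
    parts = {"box": float(box_loss.data) / denom,
             "obj": float(obj_loss.data) / denom,
             "cls": float(cls_loss.data) / denom,
             "total": float(total.data), "n_pos": n_pos}
    return total, parts


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: MitosisDetector
    log: list                               # per-iteration loss dicts
    checkpoint_path: object = None
    seed: int = 0


def _augment(img, boxes, rng, size):
    """Random horizontal/vertical flips with box remapping."""
    if rng.random() < 0.5:
        img = img[:, :, ::-1]
        boxes = [((size - x1, y0, size - x0, y1), c)
                 for (x0, y0, x1, y1), c in boxes]
    if rng.random() < 0.5:
        img = img[:, ::-1, :]
        boxes = [((x0, size - y1, x1, size - y0), c)
                 for (x0, y0, x1, y1), c in boxes]
    return np.ascontiguousarray(img), boxes


def _to_chw(img):
    return (np.asarray(img, dtype=DTYPE) / 255.0).transpose(2, 0, 1)


def train_loop(dataset, cfg: ModelConfig, seed=0, iterations=200,
               batch_size=8, checkpoint=None, augment=True, model=None,
               log_every=0):
    """Train a detector on (images, annotations) pairs.

    dataset: object with .images (uint8 HWC) and .annotations lists, or a
    (images, annotations) tuple. Fully deterministic for a fixed seed.
    Raises RuntimeError on a NaN loss.
    """
    if isinstance(dataset, tuple):
        images, annotations = dataset
    else:
        images, annotations = dataset.images, dataset.annotations
    if len(images) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    if model is None:
        model = MitosisDetector(cfg, rng=np.random.default_rng(seed))
    opt = Adam(model.parameters(), lr=cfg.lr)
    model.train()
    log = []
    n = len(images)
    size = cfg.input_size
    for it in range(iterations):
        idx = rng.choice(n, size=min(batch_size, n), replace=n < batch_size)
        batch_imgs, batch_anns = [], []
        for i in idx:
            img, boxes = _to_chw(images[i]), list(annotations[i])
            if augment:
                img, boxes = _augment(img, boxes, rng, size)
            batch_imgs.append(img)
            batch_anns.append(boxes)
        x = Tensor(np.stack(batch_imgs))
        raw = model(x)
        loss, parts = compute_loss(raw, batch_anns, cfg)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"NaN/inf loss at iteration {it}: {parts}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        parts["iter"] = it
        log.append(parts)
        if log_every and it % log_every == 0:
            print(f"iter={it} " +
                  " ".join(f"{k}={v:.4f}" for k, v in parts.items()
                           if k != "iter"))
    model.eval()
    path = None
    if checkpoint is not None:
        path = save_checkpoint(model, checkpoint, extra={"seed": seed})
    return TrainResult(model=model, log=log, checkpoint_path=path, seed=seed)


def save_checkpoint(model: MitosisDetector, path, extra=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {"config": asdict(model.cfg)}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=json.dumps(meta, default=list),
             **{k: v for k, v in state.items()})
    return path


def load_checkpoint(path) -> MitosisDetector:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfgd = meta["config"]
        for key in ("widths", "common_grid"):
            if isinstance(cfgd.get(key), list):
                cfgd[key] = tuple(cfgd[key])
        cfg = ModelConfig(**cfgd)
        model = MitosisDetector(cfg)
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    model.eval()
    return model


def detect_images(model: MitosisDetector, images, batch_size=8):
    """Run inference; returns per-image lists of Detection."""
    from .autodiff import no_grad
    model.eval()
    out = []
    with no_grad():
        for start in range(0, len(images), batch_size):
            chunk = images[start:start + batch_size]
            x = Tensor(np.stack([_to_chw(im) for im in chunk]))
            raw = model(x)
            for b in range(len(chunk)):
                out.append(decode_and_nms(raw, model.cfg, image_index=b))
    return out


def evaluate_model(model, images, annotations, iou_thresh=0.5):
    """Detect on `images` and score against `annotations` (mAP50 report)."""
    from .metrics import evaluate_detections
    dets = detect_images(model, images)
    preds = [[(d.box, d.class_id, d.confidence) for d in ds] for ds in dets]
    return evaluate_detections(preds, annotations, iou_thresh=iou_thresh)
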