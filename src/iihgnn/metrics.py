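"""COCO-style detection metrics: P, R, AP/mAP50, ACC, F1, confusion matrix.

Definitions follow the standard detection conventions: a prediction is a
true positive when it is the first (highest-confidence) detection to
overlap an unmatched ground-truth box of its class with IoU at or above
the threshold; each ground truth matches at most once. Then

    Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
    AP  = area under the precision-recall curve (all-point interpolation)
    mAP = mean AP over classes
    ACC = (TP + TN) / (TP + FP + FN + TN)
    F1  = 2 P R / (P + R)

Edge conventions (the formulas above are undefined there): P = 1 with no
predictions, R = 1 with no ground truths, F1 = 0 when P + R = 0. True
negatives are ill-defined for a detector; ACC counts TN at patch level —
an image with neither ground truths nor detections is one TN.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult", "PRCurve", "box_iou", "match_detections",
    "precision_recall", "average_precision", "mean_ap", "acc_f1",
    "pr_curve_from_detections", "confusion_matrix", "evaluate_detections",
]


def box_iou(a, b) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


@dataclass
class MatchResult:
    """Confusion counts at a fixed IoU threshold, plus per-detection flags
    (True = matched a ground truth) in descending-confidence order."""
    TP: int
    FP: int
    FN: int
    TN: int = 0
    pred_is_tp: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    pred_conf: np.ndarray = field(default_factory=lambda: np.zeros(0))


def match_detections(preds, gts, iou_thresh=0.5) -> MatchResult:
    """Greedy one-to-one matching in descending confidence.

    preds: [(box, class_id, confidence), ...]; gts: [(box, class_id), ...].
    A prediction matches the highest-IoU still-unmatched ground truth of
    its own class when that IoU >= iou_thresh.
    """
    if not (0 < iou_thresh <= 1):
        raise ValueError("iou_thresh must be in (0, 1]")
    order = np.argsort([-p[2] for p in preds], kind="stable")
    flags = np.zeros(len(preds), dtype=bool)
    confs = np.array([preds[i][2] for i in order], dtype=float)
    gt_used = np.zeros(len(gts), dtype=bool)
    if gts:
        gt_boxes = np.array([g[0] for g in gts], dtype=float)
        gt_cls = np.array([g[1] for g in gts])
    for rank, i in enumerate(order):
        box, cls, _ = preds[i]
        if not gts:
            continue
        cand = np.flatnonzero((gt_cls == cls) & ~gt_used)
        if cand.size == 0:
            continue
        ious = box_iou([box], gt_boxes[cand])[0]
        j = int(np.argmax(ious))
        if ious[j] >= iou_thresh:
            gt_used[cand[j]] = True
            flags[rank] = True
    tp = int(flags.sum())
    return MatchResult(TP=tp, FP=len(preds) - tp, FN=len(gts) - tp,
                       pred_is_tp=flags, pred_conf=confs)


def precision_recall(m: MatchResult):
    p = 1.0 if (m.TP + m.FP) == 0 else m.TP / (m.TP + m.FP)
    r = 1.0 if (m.TP + m.FN) == 0 else m.TP / (m.TP + m.FN)
    return p, r


def acc_f1(m: MatchResult):
    total = m.TP + m.FP + m.FN + m.TN
    acc = 1.0 if total == 0 else (m.TP + m.TN) / total
    p, r = precision_recall(m)
    f1 = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return acc, f1


@dataclass
class PRCurve:
    """Precision-recall sweep over detection confidence for one class."""
    recall: np.ndarray
    precision: np.ndarray
    ap: float
    class_id: int = 0


def average_precision(recall, precision) -> float:
    """All-point interpolated area under a P-R curve.

    The precision envelope (running max from the right) is integrated over
    the recall increments — the COCO convention."""
    r = np.concatenate([[0.0], np.asarray(recall, float), [1.0]])
    p = np.concatenate([[1.0], np.asarray(precision, float), [0.0]])
    # envelope
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.flatnonzero(r[1:] != r[:-1]) + 1
    return float(np.sum((r[idx] - r[idx - 1]) * p[idx]))


def mean_ap(aps) -> float:
    aps = list(aps)
    return float(np.mean(aps)) if aps else 0.0


def pr_curve_from_detections(is_tp, conf, n_gt, class_id=0) -> PRCurve:
    """P-R sweep from pooled per-detection TP flags and confidences."""
    is_tp = np.asarray(is_tp, dtype=bool)
    conf = np.asarray(conf, dtype=float)
    order = np.argsort(-conf, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt if n_gt > 0 else np.zeros_like(tp, dtype=float)
    precision = tp / np.maximum(tp + fp, 1)
    if n_gt == 0 or is_tp.size == 0:
        ap = 1.0 if (n_gt == 0 and is_tp.size == 0) else 0.0
    else:
        ap = average_precision(recall, precision)
    return PRCurve(recall=recall, precision=precision, ap=ap,
                   class_id=class_id)


def confusion_matrix(preds_by_image, gts_by_image,
                     class_names=("mitotic", "hard_negative"),
                     iou_thresh=0.5) -> np.ndarray:
    """Object-level confusion matrix with a background row/column.

    Rows are truth, columns prediction; the last row/column is background.
    Matching is class-agnostic greedy by confidence: a matched pair lands
    at (truth class, predicted class); unmatched ground truths fall in the
    background column, unmatched predictions in the background row.
    """
    C = len(class_names)
    M = np.zeros((C + 1, C + 1), dtype=int)
    for preds, gts in zip(preds_by_image, gts_by_image):
        for _, cls, _ in preds:
            if not (0 <= int(cls) < C):
                raise ValueError(f"unknown class id {cls}")
        for _, cls in gts:
            if not (0 <= int(cls) < C):
                raise ValueError(f"unknown class id {cls}")
        order = np.argsort([-p[2] for p in preds], kind="stable")
        gt_used = np.zeros(len(gts), dtype=bool)
        pred_matched = np.zeros(len(preds), dtype=bool)
        if gts:
            gt_boxes = np.array([g[0] for g in gts], dtype=float)
        for i in order:
            box, pcls, _ = preds[i]
            if not gts:
                break
            free = np.flatnonzero(~gt_used)
            if free.size == 0:
                break
            ious = box_iou([box], gt_boxes[free])[0]
            j = int(np.argmax(ious))
            if ious[j] >= iou_thresh:
                gt_used[free[j]] = True
                pred_matched[i] = True
                M[int(gts[free[j]][1]), int(pcls)] += 1
        for j, (_, gcls) in enumerate(gts):
            if not gt_used[j]:
                M[int(gcls), C] += 1
        for i, (_, pcls, _) in enumerate(preds):
            if not pred_matched[i]:
                M[C, int(pcls)] += 1
    return M


def evaluate_detections(preds_by_image, gts_by_image, iou_thresh=0.5,
                        classes=None) -> dict:
    """Dataset-level report: per-class AP, mAP50, P, R, ACC, F1, confusion.

    preds_by_image: per image [(box, class, conf), ...];
    gts_by_image: per image [(box, class), ...].
    """
    if classes is None:
        classes = sorted({c for gts in gts_by_image for _, c in gts} |
                         {c for ps in preds_by_image for _, c, _ in ps}) or [0]
    per_class = {}
    tot = MatchResult(0, 0, 0)
    tn = 0
    for preds, gts in zip(preds_by_image, gts_by_image):
        if not preds and not gts:
            tn += 1
    for c in classes:
        flags, confs, n_gt = [], [], 0
        for preds, gts in zip(preds_by_image, gts_by_image):
            p_c = [p for p in preds if p[1] == c]
            g_c = [g for g in gts if g[1] == c]
            m = match_detections(p_c, g_c, iou_thresh)
            flags.append(m.pred_is_tp)
            confs.append(m.pred_conf)
            n_gt += len(g_c)
            tot.TP += m.TP
            tot.FP += m.FP
            tot.FN += m.FN
        curve = pr_curve_from_detections(
            np.concatenate(flags) if flags else np.zeros(0, bool),
            np.concatenate(confs) if confs else np.zeros(0), n_gt, c)
        per_class[c] = curve
    tot.TN = tn
    p, r = precision_recall(tot)
    acc, f1 = acc_f1(tot)
    return {
        "per_class_ap": {c: per_class[c].ap for c in classes},
        "mAP50": mean_ap(per_class[c].ap for c in classes),
        "precision": p, "recall": r, "ACC": acc, "F1": f1,
        "counts": {"TP": tot.TP, "FP": tot.FP, "FN": tot.FN, "TN": tot.TN},
        "curves": per_class,
    }
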