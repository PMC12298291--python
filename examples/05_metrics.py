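"""Detection metrics on a small hand-checkable fixture.

One image, three ground truths, four predictions with one duplicate,
one class confusion and one background false alarm.
"""
import numpy as np

from iihgnn import confusion_matrix, evaluate_detections

gts = [[((10, 10, 30, 30), 0),       # mitosis, found twice
        ((50, 50, 70, 70), 0),       # mitosis, called hard-negative
        ((90, 90, 110, 110), 1)]]    # hard negative, found
preds = [[((10, 10, 30, 30), 0, 0.95),
          ((11, 11, 31, 31), 0, 0.60),   # duplicate -> false positive
          ((50, 50, 70, 70), 1, 0.80),   # wrong class
          ((90, 90, 110, 110), 1, 0.90),
          ((130, 130, 150, 150), 0, 0.40)]]   # background false alarm

rep = evaluate_detections(preds, gts)
print(f"P: {rep['precision']:.3f}  R: {rep['recall']:.3f}  "
      f"F1: {rep['F1']:.3f}  mAP50: {rep['mAP50']:.3f}")
print(f"counts: {rep['counts']}")
cm = confusion_matrix(preds, gts)
print("confusion (rows = truth mitotic/hard-neg/background):")
print(np.array2string(cm))
# Matching is greedy in confidence and one-to-one per class, so the
# duplicate and the wrong-class call both count as false positives; the
# confusion matrix shows the class swap explicitly.
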