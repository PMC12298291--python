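# Methods

## The detection model

The detector is a single-stage, anchor-free network for 2-class object
detection (mitotic figure, hard negative) in RGB histology patches.

**Backbone.** Five stride-2 stages produce maps at strides 4–32; the
three deepest (P3–P5, strides 8/16/32) feed the head. Stage blocks are
either C3K2 (split–bottleneck–merge) or BBMM. A BBMM block runs three
branches on the same input — the C3K2 path, a 1×1 convolution
(channel recalibration, no spatial mixing) and a 3×3 deformable
convolution — and fuses them by channel concatenation + 1×1 projection
(`bbmm.fusion: sum` is the lighter alternative). The deformable branch's
offset predictor is zero-initialised so it starts as an exact plain
convolution; which stages use BBMM is configurable
(`bbmm.replace_stages`), default all backbone stages, with the reduced
preset using P3–P5 where the spatial cost is low.

**Hypergraph neck.** The five-map pyramid (P6/P7 are either real extra
stages, `model.five_stage: true`, or average-pooled copies of P5) is
bilinearly resampled to a common grid — by default the middle pyramid
stage's grid, or an explicit `HxW` — and concatenated channel-wise into
the hybrid matrix X_m (one row per grid position, C_m = ΣC_i columns).
One hyperedge is anchored at each vertex v and contains every vertex
within Euclidean distance λ of it in feature space (strict inequality;
the anchor always belongs to its own hyperedge; duplicate hyperedges are
retained, so |E| = |V|). Distances use the raw concatenated features —
no normalisation step is applied — so the useful range of λ depends on
feature magnitudes; batch normalisation upstream keeps those near unit
scale, and λ = 8 is the default operating point. The convolution is

    X' = X + Dv⁻¹ H De⁻¹ Hᵀ X Θ

computed per image (the incidence structure is image-specific and is
rebuilt from the current features on every forward pass; gradients flow
through the aggregation, not through the discrete construction). Zero
degrees are pseudo-inverted: a vertex in no hyperedge, or an empty
hyperedge, contributes nothing and the residual passes through, so a
degenerate λ cannot crash a run. Θ is shared across hyperedges — this is
what makes the explicit per-hyperedge form and the matrix form the same
operator (tested to 1e-5 on random instances) — and is zero-initialised
so the layer starts as the identity and training decides how much
context to inject. The grid output returns to the three head scales by
bilinear resizing plus a per-scale 1×1 projection.

**Bottom-up fusion and head.** Neck outputs are added to the matching
backbone maps; the fused P3 map is then pushed downward with stride-2
convolutions (P3→P4→P5) so high-resolution detail survives to the
coarser scales. Each head cell predicts sigmoid center offsets,
log-scale width/height, an objectness logit and per-class logits.

**Confidence.** The score of a detection is defined as
Pr(object) × IoU(predicted box, truth). During training the objectness
target at an assigned cell is the IoU of the decoded box with its
ground truth, so the learned objectness approximates that product; at
inference the reported confidence is sigmoid(objectness) ×
sigmoid(class), because the true IoU is unobservable.

**Loss and assignment.** Each ground truth is assigned to the scale
whose stride best matches its size and to the cell containing its
center. The loss is (5·IoU-loss + objectness BCE + class BCE) / #positives,
with non-positive cells down-weighted (0.15) in the objectness term.
Optimisation uses Adam (default lr 3e-3; 5e-3 in the reduced preset),
batch 8, with horizontal/vertical flip augmentation. A NaN loss aborts
with a diagnostic. Training is bit-deterministic for a fixed seed: all
randomness (init, sampling, augmentation) flows from one
`numpy.random.Generator`.

**Decoding.** Per-class greedy NMS (default IoU 0.45) after a
confidence threshold (default 0.25), at most 300 detections, sorted by
descending confidence. Boxes are 0-based half-open pixel coordinates
`(x_min, y_min, x_max, y_max)` everywhere in the library; COCO
(`x, y, w, h` absolute) and YOLO (normalised center format) conventions
exist only at the file-format boundary.

## Numerical core

All layers run on a small reverse-mode autodiff engine over numpy
(float32): direct convolution by kernel-offset slicing, separable
bilinear resampling (`out = A_h x A_wᵀ` with row-stochastic interpolation
matrices, so constant maps are preserved exactly), and a deformable
convolution whose bilinear sampling is differentiable in the inputs,
the offsets and the weights (gradients verified against finite
differences). With one BLAS thread — and on the single-CPU targets this
package aims at — results are bit-reproducible.

## Evaluation conventions

Greedy confidence-ordered matching; a prediction matches the
highest-IoU unmatched ground truth of its class at IoU ≥ 0.5 (each
ground truth matches at most once). AP is the all-point interpolated
area under the precision–recall sweep (precision envelope integrated
over recall increments); mAP50 averages AP over classes. Edge
conventions, stated because the textbook formulas are undefined there:
P = 1 with no predictions, R = 1 with no ground truths, F1 = 0 when
P + R = 0; AP = 1 for an empty class with no detections, 0 when there
are ground truths but no true positive. True negatives are ill-defined
for detection, so ACC counts TN at patch level: an image with neither
ground truths nor detections. The three-class confusion matrix
(rows truth, columns prediction, background last) uses class-agnostic
greedy matching; unmatched ground truths fall in the background column,
unmatched predictions in the background row. This matrix-building rule
is a documented convention of this package.

## Tiling

Row-major tiles of a fixed size; default stride = size (no overlap),
and the last row/column is anchored to the image edge so the union of
tiles always covers the image. Boxes are duplicated into every
intersecting tile, clipped, and dropped from a tile when the clipped
area falls below 40 % of the original; boxes surviving in no tile are
counted and logged — nothing disappears silently.

## Synthetic data

The generator emulates the regime of mitosis-detection patch datasets:
a textured pink (eosin-like) background; mitotic figures as dark
basophilic eccentric ellipses, 60 % of them with a second offset lobe
(a chromosome-plate caricature); hard negatives as similarly dark,
rounder blobs; optional unlabeled round nuclei as clutter. Each image
carries a global stain/intensity factor (±35 %) emulating
scanner/staining variability, so absolute darkness is ambiguous across
images while within-image contrast stays informative. Ground-truth
boxes are the bounding boxes of the rendered half-intensity mask of
each blob. Hard-negative counts per image are derived from the mitosis
count so the dataset-level mitotic fraction — mitoses / (mitoses + hard
negatives) — approaches the configured target; the default 0.08 keeps
mitoses well under 10 % of annotated objects, and a 100-image run lands
within 5 percentage points of the target. A single seed fully
determines every image, annotation and split (70/15/15 at image level,
mirroring slide-level leakage control).

What the generator does **not** model: real chromatin texture and
nuclear pleomorphism, touching/overlapping cells, tissue architecture
(stroma, glands, necrosis), compression artefacts, and annotation
noise. Passing tests on this data therefore demonstrate that the
mechanisms work and the training loop learns — not clinical-grade
performance on real slides.

## The desk-scale training study

The study conditions, fixed as the package's reference experiment:
200 training and 50 held-out 128-px synthetic patches (scaled-down
object counts: 1–3 mitoses, 2–12 hard negatives, fraction target 0.25),
the width-reduced model (widths 8–40, common grid 8×8, BBMM at P3–P5),
500 iterations of batch 8, seeds 0/1/2. One training run takes roughly
two minutes on one CPU. The full model reaches a held-out mAP50 around
0.9 — far above the 0.5 usefulness bar.

A companion ablation trains the identical budget with λ → 0, collapsing
every hyperedge to its anchor so cross-vertex mixing vanishes. On this
task the ablated model is statistically indistinguishable from the full
one (5-seed means 0.95 vs 0.91 at this budget; both approach 1.0 when
trained to convergence). The reason is structural: at 128 px the
reduced backbone's receptive field already covers the whole patch, so
ordinary convolutional context suffices to resolve the generator's
stain ambiguity, leaving the hypergraph path nothing exclusive to
contribute — and its extra parameters slightly slow early convergence.
Demonstrating a positive context effect would require inputs much
larger than any receptive field (gigapixel-slide scale) or
deliberately crippling the CNN's field of view; the package keeps the
honest configuration and reports the comparison as measured. The λ
sweep utility (`iihgnn sweep`, default grid 0.0001–64 including the
operating point 8) exercises the mechanism end-to-end, including the
degenerate-connectivity regime.

## Known limitations

* No stain normalisation; inputs are assumed roughly H&E-like.
* The CPU engine is for desk-scale experiments, not production
  training; a 640-px full-width model forward works but is slow.
* λ is in raw feature units; its useful range shifts if the feature
  distribution shifts (e.g. different widths or activations).
* Pyramidal WSI formats (SVS/NDPI) are out of scope; tiling operates on
  arrays loadable by Pillow/tifffile.
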