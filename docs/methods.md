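# Methods

`swsal` implements a semi-weakly supervised training and annotation
workflow for multi-slice grayscale volumes: a segmentation model is
pre-trained from a few fully annotated ("sparse") slices plus many
bounding-box labels, and is then used inside an iterative, active-learning
annotation loop in which a simulated expert corrects the least
self-consistent predictions. Everything is exercised end-to-end on
synthetic phantom volumes with known ground truth.

## The segmentation model

The backbone is a compact dual-head fully convolutional network written
directly in numpy with hand-derived backpropagation (im2col convolutions,
Adam updates): a shared encoder of 3×3 convolutions with dilations 1, 2,
4, …, an auxiliary edge head, and a segmentation head whose input is the
concatenation of the encoder output and the edge head's last hidden
feature map (edge guidance). Both heads emit full-resolution sigmoid
probability maps, so the input/output contract holds for any image size.
Defaults are `base_channels=8`, `depth=3` — about 4k parameters, enough
for two-tissue phantoms while remaining trainable on one CPU core in
seconds to minutes. Output biases are initialized to −2 because both heads
predict rare foreground classes; this shortens the early plateau when the
foreground occupies a few percent of the image. Parameters are float32 by
default (a float64 mode exists and is used by the finite-difference
gradient tests). All layer gradients are verified against central finite
differences.

## Losses

* **Area loss** `L_area = L_BCE + L_DICE`: mean binary cross-entropy plus
  a smoothed Dice loss `1 − (2Σ GQ + ε)/(Σ G + Σ Q + ε)` with `ε = 1e-6`.
  Predictions are clipped to `[1e-7, 1−1e-7]` before logarithms; the Dice
  term sees the raw prediction so the empty-label/empty-prediction case is
  exactly 0. Cross-entropies are implemented in the standard negated
  (minimizable) form. Sums are normalized by pixel count so the joint
  schedule's weights are independent of image size.
* **Edge loss**: weighted BCE with `w0 = |E|/(WH)` on the edge-positive
  term and `w1 = 1 − w0` on the background term. Since edges are rare this
  *down-weights* the positive class — the opposite of usual class
  balancing — but it is kept as the reference behaviour;
  `edge_weight_swap=True` exchanges the weights for conventional
  balancing. Which behaviour is preferable is an open question; both are
  provided and the default is the literal form.
* **Joint loss** `α·(pseudo area + pseudo edge) + β·(true area + true
  edge)` with `α = max((E_thres − E_cur)/E_thres, 0)` and
  `β = min(E_cur/E_thres, 1)`: supervision moves linearly from the
  abundant-but-noisy pseudo-labels to the few exact sparse labels over the
  first `E_thres` rounds.

## Bounding boxes to pseudo-masks

A box is converted to a pseudo-mask by seeded region growing confined to
the box. Seeds: box centre for the compact "bone" tissue; for the thin
"cartilage" tissue, Canny edges are detected inside the box (sigma 1.0,
hysteresis thresholds at the 50th/90th intensity percentiles of the box)
and the seed is the vertical midpoint of the column with the largest
top-to-bottom edge extent — the thickest part of the band. Growth admits
8-connected neighbours whose intensity is within a tolerance of the
running region mean; the tolerance starts at 0.05 and is raised by 0.05
until the region reaches `area_ratio_stop` × box area (0.8 for bone, 0.6
for cartilage), which guarantees termination. The "longitudinal" direction
is image-vertical by convention. Failures (no edges, area target
unreachable) fall back gracefully and are flagged in a confidence report.

The stop rule is read as *area ≥ ratio × box area*; the alternative
reading (area ≥ box area, with 0.8/0.6 as something else) would make the
rule unsatisfiable inside the box for the 0.8 case and is rejected.

## Three-stage pre-training

1. **Sparse stage** — train on every (S_int+1)-th slice with area + edge
   loss; edge labels derive from masks by the 8-neighbour rule (a
   foreground pixel is edge iff any of its 8 neighbours, with out-of-image
   treated as background, is background).
2. **Box stage** — train on region-grown pseudo-masks with the area loss
   only; the edge head is frozen (pseudo-edges are too noisy to
   supervise): its parameters receive no updates while gradients still
   flow through its activations. Then *pseudo-label self-refinement*:
   `refine_cycles` times, every pseudo-mask is replaced by the net's
   binarized prediction (threshold 0.5; an originally empty slice stays
   empty) and the net retrained; the returned refined set is the final
   net's own prediction. `refine_cycles=0` trains on the raw pseudo-masks
   and leaves them unchanged (the no-refinement baseline).
3. **Joint stage** — per round, a pseudo-set pass weighted by α (now with
   pseudo-edge supervision from the refined masks) alternates with a
   sparse-set pass weighted by β.

"Rounds" are epochs over the respective training set. Optimizer defaults:
Adam, learning rate 5e-4, weight decay 1e-4, β₁ 0.9, early stopping on
validation Dice with patience 20 and best-checkpoint restore; the incoming
parameters count as the round −1 checkpoint, so a stage can never end
worse on validation than it began. Every stage is deterministic given the
config seed.

## Iterative annotation loop

For each case the model predicts all unannotated slices; annotated slices
contribute their true masks. Each slice scores the mean Dice of its mask
against its neighbours' (single neighbour at stack ends; a single-slice
case scores 0 and is always selected). Slices scoring below `Dice_TS` are
selected; the simulated doctor corrects every (interval+1)-th of them by
substituting ground truth. `Dice_TS` rises linearly from its start value
(default 0.7) to exactly 1 at the final round; the interval steps down by
1 per round from its start (default 3) and must reach 0 by the final
round — schedules that cannot terminate are rejected at validation time.
At the final round (threshold 1) every remaining slice is selected, so the
loop always ends with all slices annotated. Retraining between rounds uses
the true-label loss on all annotated slices, warm-starting from the
previous round's model by default (`warm_start=False` re-initializes from
the config seed each round; whether annotation loops should warm-start is
genuinely open — warm starts are cheaper, cold starts forget early-round
biases).

An equal-budget comparison mode corrects exactly `b` slices per case per
round — the active-learning strategy picks the lowest-scoring ones, the
baseline the first in stack order — bypassing threshold and interval so
both strategies spend identical correction effort.

Workload accounting: one full slice mask is taken to cost 15 box
annotations, so `S_eq = S_s + floor(S_bb/15)`; the exact rational value is
also available.

## The phantom generator

Each case is a stack of slices containing a compact bright "bone" (a
filled ellipse whose radius is modulated by three low-order angular
harmonics) and a thin "cartilage" band (2–6 px) hugging an arc near the
top of the bone boundary, thickest at the arc centre so image columns
cross it once and its thickest column is well defined. Intensities:
background 0.25, bone 0.85, cartilage 0.55, plus a smooth intensity
inhomogeneity (a random linear ramp plus a broad Gaussian blob, peak
amplitude 0.12) emulating MRI coil bias fields, Gaussian boundary blur
(sigma 1.0), and additive noise (sigma 0.03); each case is then min-max
standardized to exactly [0, 1]. All shape and bias parameters follow a
per-slice random walk with step scale `inter_slice_drift` (default 0.5
px), which produces the adjacent-slice similarity the scoring rule relies
on; drift 0 freezes the anatomy exactly. Same seed ⇒ bit-identical output.

What the phantom does *not* emulate: MRI physics (no partial volume,
ghosting, or coil arrays), anatomical variability beyond smooth ellipse
perturbations, more than two tissues, and pathology. Passing the property
suites therefore shows that the training and annotation machinery behaves
as designed under the assumed statistical structure (adjacent-slice
similarity, compact-vs-thin tissues, imperfect box-derived pseudo-labels),
not that the pipeline reaches any particular accuracy on clinical data.

## Problem sizes used by the test suite

The property experiments (self-refinement benefit, supervision ordering,
selection-strategy comparison) run on 6 cases of 10 slices at 48×48 px,
split 3/1/2 into train/validation/test, sparse interval 3, with 60–100
training rounds and results averaged over 3 seeds — sizes chosen so the
whole suite runs on a single CPU core in minutes while keeping the phantom
structures (bone radius ~10–12 px, cartilage 2–6 px) resolvable.

## Known limitations

* The backbone is deliberately small; it is not a feature-pyramid
  network, and its capacity bounds achievable Dice on harder phantoms.
* Region growing assumes the tissue is the intensity-dominant structure
  inside its box; heavily textured interiors would need a different
  homogeneity criterion.
* The simulated doctor is a perfect oracle; real corrections carry their
  own noise.
* Per-tissue models are independent binary segmenters; no label-exclusion
  constraint is enforced between tissues.
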