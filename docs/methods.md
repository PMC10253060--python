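# Methods

## Problem and protocol

The package targets 4-class retinal-disease screening (Normal, Glaucoma,
AMD, Diabetic Retinopathy) on a corpus pooled from many sources, where
the class census is severely skewed toward Normal and DR. The core
procedure is two-stage learning:

* **Threshold split.** Let *t* be the corpus count of the threshold
  class (glaucoma by default). For Normal and DR, a uniform random
  sample of min(*t*, class count) is routed to the fine-tuning subset
  and the excess to pre-training; glaucoma and AMD go to fine-tuning in
  full. The split is exhaustive, disjoint, and seeded. Which particular
  excess images go to pre-training is a uniform random choice — the rule
  only fixes the counts — so a seed is part of the protocol.
* **Stage 1 (pre-training).** Binary Normal-vs-DR training on the excess
  subset, weighted cross-entropy 1:2 (favouring DR), internal stratified
  90/10 train/validation split.
* **Stage 2 (fine-tuning).** The classification head is replaced by a
  4-output layer, the freeze rule is re-applied, and training continues
  on the balanced subset with class weights 1 / 0.9 / 1.5 / 1.2 in the
  canonical order (Normal, Glaucoma, AMD, DR).

Both stages share one recipe: rectified Adam (β = 0.9/0.999, lr
3×10⁻⁴, batch 32, weight decay 10⁻⁵ added to the gradient), cosine
annealing η(t) = η_min + ½(η_max − η_min)(1 + cos(πt/T_max)) with
T_max = 20, η_min = 10⁻⁵, η_max = 3×10⁻⁴, stepped per epoch; early
stopping on validation loss with patience 5, restoring the best-epoch
weights. Beyond T_max the cosine expression is simply continued, so a
run longer than one cycle re-warms the learning rate — the behaviour of
the warm-restart scheduler family this annealing rule comes from. In
practice the second cycle is what lets the small fine-tuning sets
(hundreds of images) reach usable minority-class sensitivity; with the
rate clamped at η_min nothing moves after epoch 20.

The weighted cross-entropy batch reduction divides by the summed weights
of the batch (weighted mean), so with unit weights it equals the plain
mean cross-entropy; probabilities are floored at 10⁻¹² rather than
raising on log 0.

### Freezing

"Freeze half of the feature extractor" is interpreted as the first
⌈fraction · L⌉ of the L ordered layer *blocks* (by depth), not by
parameter count. Pipeline defaults: stage 1 freezes nothing (it starts
from random initialization — there are no generic pretrained features to
protect), stage 2 freezes half (protecting the stage-1 features), and
the ROS/RUS arms freeze nothing (they have no earlier stage). Frozen
parameters receive no optimizer updates; batch-norm running statistics
keep updating, as is conventional.

## Backbone

The desk-scale backbone (`tiny-cnn`) is four conv blocks (3×3
convolution, per-channel batch normalization, ReLU, 2×2 max pool;
channels 8/16/32/64) and a linear head, ~25k parameters, implemented in
the package's own numpy layer library (nine-shift tensor contractions
for convolution; gradients verified against finite differences). Batch
normalization is part of the design because, without large-scale
pretraining, the plain stack underfits badly within the epoch budget.
ImageNet-scale backbones (ResNet50, ConvNextTiny, RegNetY-3.2GF) are
accommodated through `register_backbone`; reproducing published
real-data metrics with them is explicitly out of scope here.

## Preprocessing and augmentation

Images are stretched (aspect not preserved; a deliberate simplification,
since the synthetic field is centred) to a square target and
standardized per channel with the fixed ImageNet-1K statistics. The
pipeline default target is 32 px — the synthetic images carry their
signal at that scale and training cost grows with the square of the
side; the config accepts 224 for real-data work.

Sizes are unified before the training loop; augmentation then operates
on the resized images. It applies, in fixed order and each with its own
probability: rotation (p = 0.8, ±90°, bilinear, zero fill — the fundus
background is black), horizontal/vertical flips (p = 0.5), brightness/
contrast jitter (p = 0.5; x·(1+c) + b·255 with b ~ U(−0.1, 0.1),
c ~ U(−0.15, 0.15), clipped), and cutout (p = 0.5, 20 holes, max
11×11 px **at the 224 px reference resolution**; hole sides scale with
the actual image side so the occluded fraction is resolution-invariant —
unscaled 11 px holes would blank ~30% of a 64 px image). No augmentation
is ever applied at validation or test time.

## Synthetic corpus

The generator emulates what the downstream stages need from real merged
fundus corpora, not photorealism:

* circular bright retina field on a dark background; radial shading;
  random-walk vessels leaving the optic disc; a darker macula;
* class conditioning: the cup-to-disc **area** ratio is drawn from
  (0.10, 0.30) for non-glaucoma and the disjoint (0.55, 0.80) for
  glaucoma; DR adds 4–9 bright exudate-like blobs and 4–9 dark
  hemorrhage-like dots, kept off the disc and mutually separated so each
  is a distinct connected component; AMD adds 5–9 yellowish drusen-like
  deposits near the field centre;
* acquisition artifacts: per-image multiplicative exposure in
  [0.5, 1.5], additive Gaussian pixel noise (sd 6 on the 0–255 scale),
  and 10% of images rendered at 1.5× resolution then resized by the
  pipeline — emulating under-/over-exposure and multi-camera resolution
  heterogeneity. The source corpora give no quantitative artifact
  severities; these ranges are package defaults chosen to be visibly
  disruptive yet leave a nearest-class-mean classifier clearly above
  chance (the documented learnability floor).

Geometry is rendered analytically, so each image carries ground-truth
metadata (disc/cup pixel areas, lesion coordinates) used by the test
oracles. Setting the class-specific ranges equal
(`SynthesisParams.null_signal()`) renders the classes indistinguishable,
giving a null condition under which classifiers must fall back to
chance. What passing tests on this corpus shows is that the *protocol*
behaves as designed under controlled imbalance; it says nothing about
label noise, co-pathology, camera colour profiles or other properties of
real fundus photographs.

## Evaluation

Folds are stratified by class (with ~5% AMD, unstratified folds could
lack AMD entirely, making validation loss ill-defined); iteration *i*
uses fold *i* as test and fold (*i*+1) mod k as validation — a
deterministic reading of "a different part … another part". Per-class
metrics use the one-vs-rest reduction of the 4×4 confusion matrix;
"accuracy" per class is the one-vs-rest (TP+TN)/total. AUC is the
rank-sum (Mann–Whitney) statistic on the softmax probability of the
target class, ties half-weighted, which equals the trapezoidal ROC area.
Degenerate 0/0 ratios are returned as 0 (sensitivity, F1) or 100
(specificity) with a flag rather than NaN. Aggregation reports mean ±
standard deviation over folds with the population convention (ddof = 0,
a descriptive statistic over the k folds; switchable). ROC bands
interpolate each fold's curve onto a fixed 101-point FPR grid and report
pointwise mean and sd.

## Comparison of imbalance strategies

ROS duplicates minority *records* (same underlying image referenced
again) up to the maximum class count; RUS subsamples majority classes
without replacement down to the minimum. Both touch training folds only.
Validation/test folds are thresholded — Normal and DR capped at the
fold's glaucoma count — so every arm is scored on identical, comparably
balanced data; the two-stage arm re-runs its split and pre-training
inside each iteration's training folds so its evaluation data are never
seen during pre-training. When only the two-stage protocol is requested,
the pipeline instead performs one global split, one pre-training pass,
and k-fold CV over the fine-tuning subset.

## Problem sizes and numerical choices

The shipped comparison experiment uses a 2,200-image synthetic corpus
(1,200 / 300 / 100 / 600 — the qualitative imbalance structure of the
real merged corpus at a size nine models can be trained on in about ten
CPU-minutes), 64 px renders, 32 px training inputs, 3-fold CV, epoch
caps of 20 (stage 1) and 40 (stage 2 and the resampling arms; two
annealing cycles). Chance bands for "above chance" claims are permutation
nulls (500 label permutations, mean + 3 sd). Tests freeze all seeds;
training is single-threaded and bit-reproducible, and reruns of a
pipeline config produce byte-identical summaries.

## Known limitations

* The bundled backbone is deliberately small; absolute metric values on
  the synthetic corpus are not comparable to published real-data values.
* The synthetic classes are mutually exclusive and noise-free in their
  labels, unlike real merged corpora.
* ROS at scale multiplies epoch cost by the imbalance ratio; the
  package mitigates this only by duplicating references, not pixels.
* Resize stretches rather than letterboxes; for heavily non-square real
  images this distorts geometry.
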