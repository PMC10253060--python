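# fundusbalance

Class-imbalance-aware training and evaluation for 4-class retinal fundus
image classification (Normal, Glaucoma, AMD, Diabetic Retinopathy).

Screening models for the most prevalent retinal diseases are best trained
on large corpora pooled from many public datasets — but pooling
aggravates class imbalance: merged public collections hold on the order
of 86k normal and 34k diabetic-retinopathy images against only ~3.8k
glaucoma and ~600 AMD images. This package implements a two-stage
protocol for that regime, plus the classical resampling baselines and a
rigorous one-vs-rest evaluation harness:

1. **Threshold split.** With threshold *t* = the glaucoma cardinality,
   the excess Normal and DR images above *t* form a **pre-training**
   subset; the remaining *t* Normal, *t* DR, all glaucoma and all AMD
   images form a balanced **fine-tuning** subset. On the published class
   totals (86,415 / 3,787 / 632 / 34,379) this yields an 11,993-image
   fine-tuning set (3,787 / 3,787 / 632 / 3,787) and a pre-training set
   with 30,592 DR images and no glaucoma or AMD.
2. **Stage one** trains a binary Normal-vs-DR classifier on the
   pre-training subset with cross-entropy weights 1 : 2.
3. **Stage two** replaces the head with four outputs, freezes half of the
   feature extractor, and fine-tunes with class weights
   1 / 0.9 / 1.5 / 1.2 (Normal / Glaucoma / AMD / DR).
4. **Baselines.** Random minority oversampling (ROS) and random majority
   undersampling (RUS) applied to training folds only; validation/test
   folds are *thresholded* so Normal and DR match the fold's glaucoma
   count.
5. **Evaluation.** Stratified k-fold cross-validation with rotating
   validation/test folds; per-class one-vs-rest accuracy, F1,
   sensitivity, specificity and AUC (rank-sum definition), macro
   averages, overall accuracy, all as mean ± sd over folds, with
   pointwise-interpolated ROC bands.

Both stages use rectified Adam (lr 3×10⁻⁴, batch 32, weight decay 10⁻⁵),
a cosine-annealed learning rate (T_max = 20, η ∈ [10⁻⁵, 3×10⁻⁴]) stepped
per epoch, augmentation applied only at training time (rotation ±90°
p=0.8, flips p=0.5, brightness/contrast jitter p=0.5, cutout p=0.5), and
early stopping on validation loss with patience 5.

Acquiring the 22 public datasets is out of scope; a **synthetic fundus
generator** stands in for them, rendering class-conditional images
(disc/cup geometry with enlarged cup-to-disc ratio for glaucoma,
exudate/hemorrhage-like lesions for DR, drusen-like central deposits for
AMD) with exposure, noise and resolution artifacts, so the whole pipeline
is testable end to end. The bundled backbone is a small
batch-normalized CNN trained with the package's own numpy layers; larger
backbones can be plugged in through `register_backbone`.

## Worked example

```python
from fundusbalance import (CLASSES, SynthesisParams, generate_corpus,
                           threshold_split)

params = SynthesisParams(image_size=64)
corpus = generate_corpus({"NORMAL": 300, "GLAUCOMA": 60, "AMD": 25, "DR": 120},
                         params, seed=7)
split = threshold_split(corpus, rng=0)
print("threshold:", split.threshold)
print("fine-tune census:", split.finetune.counts)
print("pre-train census:", split.pretrain.counts)
```

prints

```
threshold: 60
fine-tune census: {'NORMAL': 60, 'GLAUCOMA': 60, 'AMD': 25, 'DR': 60}
pre-train census: {'NORMAL': 240, 'GLAUCOMA': 0, 'AMD': 0, 'DR': 60}
```

— the fine-tuning subset is balanced at the glaucoma cardinality (AMD,
scarcer than the threshold, is kept in full), and only excess
Normal/DR images reach pre-training. A full run — generation, split,
two-stage training, cross-validated evaluation and the ROS/RUS arms — is
one call (or `fundusbalance run --config cfg.yaml --out run/`):

```python
from fundusbalance import PipelineConfig, run_pipeline

cfg = PipelineConfig(counts={"NORMAL": 300, "GLAUCOMA": 60, "AMD": 25, "DR": 120},
                     k=3, methods=["twostage", "ros", "rus"])
results = run_pipeline(cfg, "run/")
mean, sd = results["twostage"]["summary"].macro["f1"]
```

The run directory contains the resolved config, the manifest, the fold
plan, per-method metric tables (`comparison.csv`), ROC-band data and a
machine-readable `summary.json`; identical configs and seeds reproduce it
byte-for-byte.

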