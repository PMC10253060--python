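"""Random over-/under-sampling baselines and evaluation-fold thresholding.

ROS equalizes class counts upward by duplicating minority records with
replacement; RUS equalizes downward by discarding majority records
without replacement.  Both touch only training data.  Validation and
test folds are instead *thresholded*: Normal and DR are downsampled to
the fold's glaucoma cardinality so evaluation class ratios match the
fine-tuning regime.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .corpus import CorpusManifest, ManifestError, ThresholdClassMissingError
from .labels import DR, GLAUCOMA, NORMAL, check_label

__all__ = ["ros", "rus", "threshold_eval_fold"]


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _class_indices(manifest: CorpusManifest) -> dict[str, np.ndarray]:
    labels = np.array([r.label for r in manifest])
    present = {}
    for label in dict.fromkeys(labels):
        present[label] = np.flatnonzero(labels == label)
    return present


def ros(train: CorpusManifest, rng=0) -> CorpusManifest:
    """Random minority oversampling to the maximum class count.

    All original records are retained; added records are duplicates of
    originals (same file/pixels) with a ``~r<i>`` id suffix to keep
    manifest ids unique.
    """
    if len(train) == 0:
        raise ManifestError("cannot resample an empty manifest")
    rng = _rng(rng)
    per_class = _class_indices(train)
    target = max(len(v) for v in per_class.values())
    records = list(train.records)
    for label, idx in per_class.items():
        deficit = target - len(idx)
        if deficit > 0:
            extra = rng.choice(idx, size=deficit, replace=True)
            for i, src in enumerate(extra):
                r = train.records[src]
                records.append(replace(r, id=f"{r.id}~r{i}"))
    return CorpusManifest(records)


def rus(train: CorpusManifest, rng=0) -> CorpusManifest:
    """Random majority undersampling to the minimum class count (no replacement)."""
    if len(train) == 0:
        raise ManifestError("cannot resample an empty manifest")
    rng = _rng(rng)
    per_class = _class_indices(train)
    target = min(len(v) for v in per_class.values())
    keep = []
    for idx in per_class.values():
        if len(idx) > target:
            keep.extend(rng.choice(idx, size=target, replace=False))
        else:
            keep.extend(idx)
    return train.subset(sorted(keep))


def threshold_eval_fold(
    fold: CorpusManifest, threshold_class: str = GLAUCOMA, rng=0
) -> CorpusManifest:
    """Cap Normal and DR at the fold's threshold-class count.

    Glaucoma and AMD are never touched; the result matches the class
    ratios of the fine-tuning regime so that evaluation is comparable
    across training strategies.
    """
    check_label(threshold_class)
    counts = fold.counts
    t = counts[threshold_class]
    if t == 0:
        raise ThresholdClassMissingError(
            f"threshold class {threshold_class!r} absent from evaluation fold"
        )
    rng = _rng(rng)
    labels = np.array([r.label for r in fold])
    keep = np.ones(len(labels), dtype=bool)
    for label in (NORMAL, DR):
        if label == threshold_class:
            continue
        idx = np.flatnonzero(labels == label)
        if idx.size > t:
            kept = rng.choice(idx, size=t, replace=False)
            keep[idx] = False
            keep[kept] = True
    return fold.subset(np.flatnonzero(keep))
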