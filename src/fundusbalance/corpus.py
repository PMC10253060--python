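"""Corpus manifests: pooling per-source datasets and the threshold split.

A :class:`CorpusManifest` is the unit passed between every pipeline stage:
an ordered list of labeled image records with a per-class census.  The
threshold split routes the excess majority-class images (NORMAL and DR
above the cardinality of a reference minority class, by default glaucoma)
into a binary pre-training subset, and the balanced remainder plus all
minority-class images into the 4-class fine-tuning subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import AMD, CLASSES, DR, GLAUCOMA, NORMAL, check_label

__all__ = [
    "ImageRecord",
    "CorpusManifest",
    "SplitResult",
    "ManifestError",
    "ThresholdClassMissingError",
    "class_counts",
    "pool",
    "threshold_split",
]


class ManifestError(ValueError):
    """Raised for structural manifest problems (duplicate ids, empties...)."""


class ThresholdClassMissingError(ManifestError):
    """Raised when the threshold class has no records, making the split undefined."""


@dataclass(slots=True)
class ImageRecord:
    """One labeled fundus image.

    ``pixels`` optionally carries the decoded uint8 RGB array for
    in-memory corpora; it never round-trips through the manifest CSV.
    """

    id: str
    path: str | None
    label: str
    source: str
    width: int
    height: int
    pixels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        check_label(self.label)


@dataclass
class CorpusManifest:
    """Ordered collection of :class:`ImageRecord` with a recomputable census."""

    records: list[ImageRecord]

    def __post_init__(self) -> None:
        ids = set()
        for r in self.records:
            if r.id in ids:
                raise ManifestError(f"duplicate record id {r.id!r} in manifest")
            ids.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def counts(self) -> dict[str, int]:
        return class_counts(self)

    def subset(self, indices: Iterable[int]) -> "CorpusManifest":
        rec = self.records
        return CorpusManifest([rec[i] for i in indices])

    def by_ids(self, ids: Sequence[str]) -> "CorpusManifest":
        index = {r.id: r for r in self.records}
        return CorpusManifest([index[i] for i in ids])

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "relative_path": [r.path or "" for r in self.records],
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
                "width": [r.width for r in self.records],
                "height": [r.height for r in self.records],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorpusManifest":
        df = pd.read_csv(path, keep_default_na=False)
        records = [
            ImageRecord(
                id=str(row.id),
                path=str(row.relative_path) or None,
                label=str(row.label),
                source=str(row.source),
                width=int(row.width),
                height=int(row.height),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)


@dataclass
class SplitResult:
    """Outcome of the threshold split."""

    threshold: int
    pretrain: CorpusManifest
    finetune: CorpusManifest


def class_counts(manifest: CorpusManifest | Iterable[ImageRecord]) -> dict[str, int]:
    """Exact census by label, keyed by every class in canonical order."""
    counts = dict.fromkeys(CLASSES, 0)
    records = manifest.records if isinstance(manifest, CorpusManifest) else manifest
    for r in records:
        counts[r.label] += 1
    return counts


def counts_manifest(counts: Mapping[str, int], source: str = "census") -> CorpusManifest:
    """Build a pixel-free manifest with the given per-class counts.

    Convenient for counts-level arithmetic (split bookkeeping on printed
    dataset censuses) where no image files exist.
    """
    records = []
    for label in CLASSES:
        n = int(counts.get(label, 0))
        records.extend(
            ImageRecord(f"{source}_{label.lower()}_{i:06d}", None, label, source, 0, 0)
            for i in range(n)
        )
    return CorpusManifest(records)


def pool(manifests: Sequence[CorpusManifest]) -> CorpusManifest:
    """Concatenate per-source manifests into one corpus.

    Record ids are disambiguated by prefixing the source tag; a collision
    surviving the prefixing is an error.
    """
    if not manifests:
        raise ManifestError("pool requires at least one manifest")
    records = []
    for m in manifests:
        for r in m.records:
            prefix = f"{r.source}:"
            new_id = r.id if r.id.startswith(prefix) else prefix + r.id
            records.append(replace(r, id=new_id))
    return CorpusManifest(records)  # duplicate check in __post_init__


def threshold_split(
    corpus: CorpusManifest,
    threshold_class: str = GLAUCOMA,
    rng: np.random.Generator | int | None = 0,
) -> SplitResult:
    """Split a corpus at the cardinality of ``threshold_class``.

    The threshold t is the corpus count of ``threshold_class``.  For the
    two majority classes (NORMAL, DR) a uniform random sample of size
    min(t, class count) goes to the fine-tuning subset and the excess to
    pre-training; glaucoma and AMD records all go to fine-tuning.  The
    split is exhaustive and disjoint, and reproducible under the rng seed.
    """
    check_label(threshold_class)
    if len(corpus) == 0:
        raise ManifestError("cannot split an empty corpus")
    counts = corpus.counts
    t = counts[threshold_class]
    if t == 0:
        raise ThresholdClassMissingError(
            f"threshold class {threshold_class!r} has no records; split undefined"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    labels = np.array([r.label for r in corpus.records])
    keep_finetune = np.ones(len(labels), dtype=bool)
    for label in (NORMAL, DR):
        if label == threshold_class:
            continue
        idx = np.flatnonzero(labels == label)
        if idx.size > t:
            kept = rng.choice(idx, size=t, replace=False)
            keep_finetune[idx] = False
            keep_finetune[kept] = True
    finetune = corpus.subset(np.flatnonzero(keep_finetune))
    pretrain = corpus.subset(np.flatnonzero(~keep_finetune))
    return SplitResult(threshold=t, pretrain=pretrain, finetune=finetune)
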