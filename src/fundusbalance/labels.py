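"""Canonical 4-class label vocabulary.

The class order (NORMAL, GLAUCOMA, AMD, DR) is fixed throughout the
package: it disambiguates every class-weight vector, confusion-matrix
axis and metric table.
"""

from __future__ import annotations

NORMAL = "NORMAL"
GLAUCOMA = "GLAUCOMA"
AMD = "AMD"
DR = "DR"

#: Canonical class order used for weight vectors and confusion matrices.
CLASSES: tuple[str, ...] = (NORMAL, GLAUCOMA, AMD, DR)

#: Index of each class in the canonical order.
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Binary pre-training loss weights (majority classes only).
PRETRAIN_CLASSES: tuple[str, str] = (NORMAL, DR)
PRETRAIN_WEIGHTS: tuple[float, float] = (1.0, 2.0)

#: 4-class fine-tuning loss weights in canonical order.
FINETUNE_WEIGHTS: tuple[float, float, float, float] = (1.0, 0.9, 1.5, 1.2)


class UnknownLabelError(ValueError):
    """Raised when a label is not in the 4-class vocabulary."""


def check_label(label: str) -> str:
    if label not in CLASS_INDEX:
        raise UnknownLabelError(
            f"unknown class label {label!r}; expected one of {CLASSES}"
        )
    return label
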