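import numpy as np
import pytest

from fundusbalance import CLASSES, SynthesisParams, generate_corpus
from fundusbalance.corpus import counts_manifest


@pytest.fixture(scope="session")
def clean_params():
    """Renderer params with artifacts switched off (noise-free, unit exposure,
    single resolution) so pixel-level oracles are exact."""
    return SynthesisParams(noise_sd=0.0, exposure_range=(1.0, 1.0),
                           alt_resolution_fraction=0.0)


@pytest.fixture(scope="session")
def balanced_corpus():
    """Small balanced 4-class corpus with default (noisy) artifacts."""
    return generate_corpus({c: 40 for c in CLASSES}, SynthesisParams(), seed=11)


def make_counts_manifest(counts, source="census"):
    """Pixel-free manifest for counts-level bookkeeping tests."""
    return counts_manifest(counts, source=source)
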