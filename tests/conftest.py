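"""Shared fixtures: phantoms and their segmentations are expensive enough
to build once per session and reuse across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from elvarkit import (
    DiseaseSpec,
    IndentationSpec,
    PhantomSpec,
    SegmentationParams,
    EnhancementParams,
    generate_phantom,
    segment_lungs,
)
from elvarkit.image_io import BinaryMask, CTVolume
from elvarkit.lung_segmentation import LungSegmentation
from elvarkit.interstitial_enhancement import InterstitialMap


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def make_lung_segmentation(vol: CTVolume, mask: np.ndarray) -> LungSegmentation:
    """Wrap an explicit mask as a segmentation result (for unit tests)."""
    bm = vol.new_mask(mask, "lung_final")
    return LungSegmentation(
        lung_mask=bm, L=bm.popcount(), stages={}, params_used=SegmentationParams()
    )


def make_counts_pair(L: int, I: int, shape=(2, 25, 40)):
    """A (segmentation, interstitial map) pair with exact L and I counts."""
    n = int(np.prod(shape))
    assert I <= L <= n
    lung = np.zeros(n, dtype=bool)
    lung[:L] = True
    inter = np.zeros(n, dtype=bool)
    inter[:I] = True
    vol = CTVolume(data=np.zeros(shape, np.float32), spacing=(1, 1, 1))
    seg = make_lung_segmentation(vol, lung.reshape(shape))
    imask = BinaryMask(inter.reshape(shape), vol.grid_id, "interstitium")
    imap = InterstitialMap(
        interstitium_mask=imask,
        I=I,
        score_field=np.zeros(shape, np.float32),
        params_used=EnhancementParams(),
        L=L,
    )
    return seg, imap


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def healthy_seg(healthy_phantom):
    vol, _ = healthy_phantom
    return segment_lungs(vol)


@pytest.fixture(scope="session")
def diseased_phantom():
    return generate_phantom(
        PhantomSpec(seed=11, disease=DiseaseSpec(target_fraction=0.20))
    )


@pytest.fixture(scope="session")
def diseased_seg(diseased_phantom):
    vol, _ = diseased_phantom
    return segment_lungs(vol)


@pytest.fixture(scope="session")
def indented_phantom():
    return generate_phantom(
        PhantomSpec(seed=11, organ_indentation=IndentationSpec(enabled=True, volume_mm3=2000.0))
    )


@pytest.fixture(scope="session")
def indented_seg(indented_phantom):
    vol, _ = indented_phantom
    return segment_lungs(vol)
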