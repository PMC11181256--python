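from __future__ import annotations

import numpy as np
import pytest

from eustex.image_io import AnnotatedLesion, RoiMask


def make_lesion(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    label: int = 1,
    lesion_id: str = "test",
) -> AnnotatedLesion:
    """Build a lesion directly from arrays, bypassing file I/O."""
    image = np.asarray(image, dtype=np.uint8)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    return AnnotatedLesion(
        image=image, roi=RoiMask(mask=np.asarray(mask, dtype=bool)), label=label,
        lesion_id=lesion_id,
    )


def random_masked_lesion(
    rng: np.random.Generator, size: int = 16, p_mask: float = 0.75
) -> AnnotatedLesion:
    """Random 8-bit image with a random blob-ish mask (never empty)."""
    image = rng.integers(0, 256, size=(size, size), dtype=np.uint8)
    mask = rng.random((size, size)) < p_mask
    mask[size // 2, size // 2] = True
    return make_lesion(image, mask)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
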