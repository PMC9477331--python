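"""Shared fixtures: small synthetic slides, toy patches, and tiny networks."""

from __future__ import annotations

import numpy as np
import pytest

from nucseg import SyntheticSpec, generate_synthetic_slide
from nucseg.pseudolabels import SamplePatch


@pytest.fixture(scope="session")
def small_slide():
    """A 192x192 high-quality slide with its exact instance mask."""
    spec = SyntheticSpec(n_nuclei=30, nucleus_radius_range=(5.0, 9.0), seed=11)
    return generate_synthetic_slide(spec, 192, 192)


@pytest.fixture(scope="session")
def low_quality_slide():
    spec = SyntheticSpec(
        n_nuclei=30, nucleus_radius_range=(5.0, 9.0), stain_quality="low", seed=11
    )
    return generate_synthetic_slide(spec, 192, 192)


def make_toy_patch(rng: np.random.Generator, n: int = 8) -> SamplePatch:
    """A tiny learnable patch: blue-ish blob on pink background with its label."""
    side = 2 * n
    image = np.empty((side, side, 3), dtype=np.uint8)
    image[...] = (230, 160, 190)  # pink body
    label = np.zeros((n, n), dtype=bool)
    r0, c0 = rng.integers(2, side - 4, size=2)
    rad = int(rng.integers(2, n // 2 + 1))
    yy, xx = np.mgrid[0:side, 0:side]
    blob = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad * rad
    image[blob] = (70, 50, 160)  # blue-purple nucleus
    half = n // 2
    label = blob[half : half + n, half : half + n]
    noise = rng.normal(0, 3, size=image.shape)
    image = np.clip(image.astype(float) + noise, 0, 255).astype(np.uint8)
    return SamplePatch(image=image, label=label)


@pytest.fixture()
def toy_patches():
    rng = np.random.default_rng(5)
    return [make_toy_patch(rng) for _ in range(24)]


def random_instance_map(
    rng: np.random.Generator, side: int = 16, max_objects: int = 4
) -> np.ndarray:
    """Small random instance map: overlapping rectangles, later label wins."""
    labels = np.zeros((side, side), dtype=np.int32)
    for k in range(1, int(rng.integers(0, max_objects + 1)) + 1):
        h = int(rng.integers(1, 6))
        w = int(rng.integers(1, 6))
        r = int(rng.integers(0, side - h + 1))
        c = int(rng.integers(0, side - w + 1))
        labels[r : r + h, c : c + w] = k
    # canonicalize: overwritten labels may have vanished
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out
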