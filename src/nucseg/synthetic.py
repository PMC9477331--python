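"""Parametric generator of HE-like microscopy slides with exact instance masks.

Real hematoxylin-eosin stains render nuclei blue-purple (alkaline hematoxylin),
cytoplasm pink-red (acidic eosin) and leave the extra-cellular space (ECS)
near-white.  The generator emulates that chemistry with three HSV color bands:

* nuclei      hue 220-290 deg (blue-purple), drawn as rotated ellipses,
* cytoplasm   hue 320-350 deg (pink), drawn as large background blobs,
* ECS         near-white, the remaining canvas.

``stain_quality`` mimics well- vs poorly-stained acquisitions: "low" quality
slides have paler, less saturated nuclei (compare badly-fixed clinical
material), which is exactly the regime that makes color-based pseudo-labels
and mixup augmentation interesting.

Generation is a pure function of :class:`SyntheticSpec` — the same spec always
produces bit-identical image and mask, which the test-suite relies on.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import ellipse

__all__ = [
    "SyntheticSpec",
    "generate_synthetic_slide",
    "NUCLEUS_HUE_BAND",
    "CYTOPLASM_HUE_BAND",
    "canonicalize_labels",
]

#: Inclusive hue band (degrees) that nucleus pixels fall in before noise.
NUCLEUS_HUE_BAND = (220.0, 290.0)
#: Inclusive hue band (degrees) for cytoplasm pixels before noise.
CYTOPLASM_HUE_BAND = (320.0, 350.0)

# Margin kept between sampled hues and the band edges so that 8-bit
# quantization cannot push a pixel outside the nominal band.
_HUE_MARGIN = 4.0


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic slide.

    Parameters
    ----------
    n_nuclei:
        Number of nuclei the generator attempts to place.  Crowded canvases
        may hold fewer; placement is deterministic given ``seed``.
    nucleus_radius_range:
        (min, max) semi-axis length in pixels of the elliptical nuclei.
    stain_quality:
        ``"high"`` for saturated, dark nuclei; ``"low"`` for pale ones.
    hue_jitter:
        Half-width in degrees of the per-nucleus hue perturbation.
    noise_sd:
        Standard deviation (8-bit intensity units) of additive Gaussian
        sensor noise applied to the final image.
    overlap:
        Maximum allowed overlap between neighbouring nuclei, expressed as a
        fraction of the sum of their radii.  Kept below ~0.3 so instances can
        touch (AJI is only discriminative then) without one ellipse cutting a
        predecessor in two.
    seed:
        Seed of the generator; the single source of randomness.
    """

    n_nuclei: int = 50
    nucleus_radius_range: Tuple[float, float] = (6.0, 12.0)
    stain_quality: str = "high"
    hue_jitter: float = 8.0
    noise_sd: float = 4.0
    overlap: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError(f"n_nuclei must be >= 0, got {self.n_nuclei}")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"nucleus_radius_range must satisfy 0 < min <= max, got {(lo, hi)}"
            )
        if self.stain_quality not in ("high", "low"):
            raise ValueError(
                f"stain_quality must be 'high' or 'low', got {self.stain_quality!r}"
            )
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")


def _hsv_to_rgb8(h_deg: float, s: float, v: float) -> np.ndarray:
    """One HSV color (hue in degrees) to an 8-bit RGB triplet."""
    rgb = hsv2rgb(np.array([[[h_deg / 360.0, s, v]]], dtype=float))[0, 0]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def _sample_nucleus_color(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    lo, hi = NUCLEUS_HUE_BAND
    center = rng.uniform(lo + _HUE_MARGIN + spec.hue_jitter, hi - _HUE_MARGIN - spec.hue_jitter)
    hue = float(np.clip(center + rng.uniform(-spec.hue_jitter, spec.hue_jitter),
                        lo + _HUE_MARGIN, hi - _HUE_MARGIN))
    if spec.stain_quality == "high":
        s = rng.uniform(0.55, 0.75)
        v = rng.uniform(0.40, 0.60)
    else:  # pale, weakly stained nuclei
        s = rng.uniform(0.25, 0.40)
        v = rng.uniform(0.70, 0.88)
    return _hsv_to_rgb8(hue, s, v)


def _sample_cytoplasm_color(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    lo, hi = CYTOPLASM_HUE_BAND
    hue = rng.uniform(lo + 2.0, hi - 2.0)
    if spec.stain_quality == "high":
        s, v = rng.uniform(0.18, 0.30), rng.uniform(0.82, 0.92)
    else:
        s, v = rng.uniform(0.10, 0.18), rng.uniform(0.88, 0.95)
    return _hsv_to_rgb8(hue, s, v)


def generate_synthetic_slide(
    spec: SyntheticSpec, height: int, width: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a synthetic HE-like slide and its exact instance mask.

    Returns
    -------
    image:
        ``(height, width, 3)`` uint8 RGB raster.
    mask:
        ``(height, width)`` int32 instance label map; 0 is background, k>0
        labels nucleus k.  Where nuclei overlap, the later-drawn instance
        wins.  Labels are canonicalized to a contiguous ``{0..K}`` set.
    """
    if height <= 0 or width <= 0:
        raise ValueError(f"slide dimensions must be positive, got {height}x{width}")
    if height < 64 or width < 64:
        raise ValueError(f"slide dimensions must be >= 64, got {height}x{width}")
    if spec.nucleus_radius_range[1] > min(height, width) / 2:
        raise ValueError(
            "nucleus_radius_range exceeds half the smaller slide dimension: "
            f"{spec.nucleus_radius_range[1]} > {min(height, width) / 2}"
        )

    rng = np.random.default_rng(spec.seed)

    # ECS canvas: near-white with a faint warm cast.
    image = np.empty((height, width, 3), dtype=np.uint8)
    image[...] = _hsv_to_rgb8(330.0, 0.02, 0.97)

    # Cytoplasm blobs: large pink ellipses covering most of the canvas.
    n_blobs = max(4, spec.n_nuclei // 4)
    blob_r = max(height, width) / 5.0
    for _ in range(n_blobs):
        r0 = rng.uniform(0, height)
        c0 = rng.uniform(0, width)
        ra = rng.uniform(0.6, 1.4) * blob_r
        rb = rng.uniform(0.6, 1.4) * blob_r
        rr, cc = ellipse(r0, c0, ra, rb, shape=(height, width),
                         rotation=rng.uniform(0, np.pi))
        image[rr, cc] = _sample_cytoplasm_color(rng, spec)

    # Nuclei: rotated ellipses, rejection-sampled so overlap stays bounded.
    mask = np.zeros((height, width), dtype=np.int32)
    centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    lo, hi = spec.nucleus_radius_range
    placed = 0
    attempts = 0
    max_attempts = max(200, 60 * spec.n_nuclei)
    while placed < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        ra = rng.uniform(lo, hi)
        rb = rng.uniform(lo, hi)
        r0 = rng.uniform(0, height)
        c0 = rng.uniform(0, width)
        rmax = max(ra, rb)
        ok = True
        for (pr, pc, prad) in centers:
            if np.hypot(pr - r0, pc - c0) < (1.0 - spec.overlap) * (prad + rmax):
                ok = False
                break
        if not ok:
            continue
        rr, cc = ellipse(r0, c0, ra, rb, shape=(height, width),
                         rotation=rng.uniform(0, np.pi))
        if rr.size == 0:
            continue
        placed += 1
        centers.append((r0, c0, rmax))
        image[rr, cc] = _sample_nucleus_color(rng, spec)
        mask[rr, cc] = placed

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=image.shape)
        image = np.clip(image.astype(np.float64) + noise, 0, 255).astype(np.uint8)

    return image, canonicalize_labels(mask)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel an instance map so positive labels form a contiguous 1..K set."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"instance map must be 2-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"instance map must be integer-typed, got {labels.dtype}")
    if labels.size and labels.min() < 0:
        raise ValueError("instance map must be nonnegative")
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out
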