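"""Full Mixup of training patches in HSV color space.

Mixing two HE patches directly in RGB washes out weakly stained nuclei: the
average of a saturated blue nucleus and a pale one is a pale, low-chroma pixel
that barely reads as a nucleus.  Blending in HSV keeps hue — the quantity that
identifies tissue — on its own axis: saturation and value are mixed linearly,
hue is mixed along the *shorter circular arc* (hue is an angle; a linear blend
of 350° and 10° must give 0°, not 180°).  Labels are superimposed by pixelwise
OR, so a mixed patch supervises every nucleus of both sources.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import color as skcolor

from .pseudolabels import SamplePatch

__all__ = [
    "MixupConfig",
    "channel_bounds",
    "normalize_patch",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "circular_hue_blend",
    "full_mixup",
    "maybe_mix",
]


@dataclasses.dataclass
class MixupConfig:
    """Mixing probability and blend-weight policy.

    ``probability`` is the chance each sample in a batch is replaced by a
    mixup; it lives in ``[p_min, p_max]`` because the dynamic training loop
    walks it up and down.  The blend weight lambda is either fixed or drawn
    uniformly from ``lambda_range`` (kept away from 0 and 1 so both source
    populations stay visible in the mixed patch).
    """

    probability: float = 0.5
    p_min: float = 0.1
    p_max: float = 0.9
    lambda_mode: str = "uniform"
    lambda_value: float = 0.5
    lambda_range: Tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= self.p_max <= 1.0:
            raise ValueError(
                f"need 0 <= p_min <= p_max <= 1, got ({self.p_min}, {self.p_max})"
            )
        if not self.p_min <= self.probability <= self.p_max:
            raise ValueError(
                f"probability {self.probability} outside [{self.p_min}, {self.p_max}]"
            )
        if self.lambda_mode not in ("fixed", "uniform"):
            raise ValueError(f"lambda_mode must be fixed|uniform, got {self.lambda_mode!r}")
        lo, hi = self.lambda_range
        for val in (self.lambda_value, lo, hi):
            if not 0.0 < val < 1.0:
                raise ValueError(f"lambda values must lie in (0,1), got {val}")

    def draw_lambda(self, rng: np.random.Generator) -> float:
        if self.lambda_mode == "fixed":
            return self.lambda_value
        lo, hi = self.lambda_range
        return float(rng.uniform(lo, hi))


def channel_bounds(reference: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """1st/99th per-channel intensity percentiles of a normalization reference."""
    ref = np.asarray(reference, dtype=np.float64)
    lo = np.percentile(ref, 1.0, axis=(0, 1))
    hi = np.percentile(ref, 99.0, axis=(0, 1))
    return lo, hi


def normalize_patch(
    image: np.ndarray,
    reference: Optional[np.ndarray] = None,
    bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """Rescale an 8-bit RGB patch to float [0,1] by robust percentiles.

    Each channel is linearly mapped so the 1st/99th intensity percentiles of
    the *reference* raster (the patch's source sub-graph; the patch itself
    when absent) go to 0/1, then clipped.  Precomputed ``bounds`` (lo, hi
    triplets) take precedence over ``reference``.  A constant reference
    channel has no spread to normalize by; it degenerates to mid-gray with a
    warning.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"patch must be H x W x 3, got {image.shape}")
    if bounds is None:
        bounds = channel_bounds(image if reference is None else reference)
    lo_all, hi_all = (np.asarray(b, dtype=np.float64) for b in bounds)
    img = image.astype(np.float64)
    out = np.empty_like(img)
    for ch in range(3):
        lo, hi = lo_all[ch], hi_all[ch]
        if hi <= lo:
            warnings.warn(
                f"channel {ch} is constant in the normalization reference; "
                "mapping it to mid-gray"
            )
            out[..., ch] = 0.5
        else:
            out[..., ch] = (img[..., ch] - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def rgb_to_hsv(patch: np.ndarray) -> np.ndarray:
    """RGB in [0,1] to HSV with hue in degrees [0, 360)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.min() < 0.0 or patch.max() > 1.0:
        raise ValueError(
            f"RGB values must lie in [0,1], got range [{patch.min()}, {patch.max()}]"
        )
    hsv = skcolor.rgb2hsv(patch)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def hsv_to_rgb(patch: np.ndarray) -> np.ndarray:
    """HSV (hue in degrees [0,360), S and V in [0,1]) back to RGB in [0,1]."""
    patch = np.asarray(patch, dtype=np.float64)
    h, s, v = patch[..., 0], patch[..., 1], patch[..., 2]
    if h.min() < 0.0 or h.max() >= 360.0:
        raise ValueError(f"hue must lie in [0,360), got range [{h.min()}, {h.max()}]")
    for name, chan in (("saturation", s), ("value", v)):
        if chan.min() < 0.0 or chan.max() > 1.0:
            raise ValueError(f"{name} must lie in [0,1]")
    hsv = patch.copy()
    hsv[..., 0] = hsv[..., 0] / 360.0
    return skcolor.hsv2rgb(hsv)


def circular_hue_blend(
    hue_a: np.ndarray, hue_b: np.ndarray, lam: float
) -> np.ndarray:
    """Blend hue angles along the shorter arc: result = a moved (1-lam) toward b.

    Matches the linear blend ``lam*a + (1-lam)*b`` when the two hues are less
    than 180 degrees apart, and wraps correctly otherwise (350 and 10 at
    lam=0.5 give 0, not 180).
    """
    hue_a = np.asarray(hue_a, dtype=np.float64)
    hue_b = np.asarray(hue_b, dtype=np.float64)
    delta = (hue_b - hue_a + 180.0) % 360.0 - 180.0
    return (hue_a + (1.0 - lam) * delta) % 360.0


def full_mixup(a: SamplePatch, b: SamplePatch, lam: float) -> SamplePatch:
    """Blend two sample patches in HSV space and superimpose their labels.

    Both images are percentile-normalized, converted to HSV; S and V are
    blended as ``lam*a + (1-lam)*b``, hue along the shorter circular arc with
    the same weight; the result returns to RGB (float in [0,1]).  The label is
    the pixelwise OR of the two source labels, so no nucleus is ever lost.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must lie in (0,1), got {lam}")
    if a.image.shape != b.image.shape or a.label.shape != b.label.shape:
        raise ValueError(
            f"mixup operands must share dimensions: {a.image.shape} vs {b.image.shape}"
        )
    hsv_a = rgb_to_hsv(_as_float(a.image))
    hsv_b = rgb_to_hsv(_as_float(b.image))
    mixed = np.empty_like(hsv_a)
    mixed[..., 0] = circular_hue_blend(hsv_a[..., 0], hsv_b[..., 0], lam)
    mixed[..., 1:] = lam * hsv_a[..., 1:] + (1.0 - lam) * hsv_b[..., 1:]
    rgb = np.clip(hsv_to_rgb(mixed), 0.0, 1.0)
    return SamplePatch(
        image=rgb,
        label=a.label | b.label,
        provenance=f"mix({a.provenance},{b.provenance})",
        mixed=True,
    )


def _as_float(image: np.ndarray) -> np.ndarray:
    """Normalize uint8 patches; pass through already-normalized float ones."""
    if image.dtype == np.uint8:
        return normalize_patch(image)
    return np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)


def maybe_mix(
    batch: Sequence[SamplePatch],
    config: MixupConfig,
    rng: np.random.Generator,
    pool: Optional[Sequence[SamplePatch]] = None,
) -> List[SamplePatch]:
    """Independently replace each sample by a mixup with probability ``p``.

    Partners are drawn uniformly from ``pool`` (the batch itself by default),
    excluding the sample's own position.  With a pool of one sample mixing is
    impossible and is skipped with a warning.
    """
    pool = batch if pool is None else pool
    if len(pool) <= 1:
        if config.probability > 0 and len(batch) > 0:
            warnings.warn("mixing pool has a single sample; mixup skipped")
        return list(batch)
    out: List[SamplePatch] = []
    for i, sample in enumerate(batch):
        if rng.random() < config.probability:
            j = int(rng.integers(0, len(pool)))
            if pool is batch:
                while j == i:
                    j = int(rng.integers(0, len(pool)))
            lam = config.draw_lambda(rng)
            out.append(full_mixup(sample, pool[j], lam))
        else:
            out.append(sample)
    return out
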