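"""Blend two training patches with Full Mixup in HSV space.

Hue is an angle, so it blends along the shorter circular arc; labels are
unioned so a mixed patch supervises every nucleus of both sources.
"""

import numpy as np

from nucseg import SyntheticSpec, generate_synthetic_slide
from nucseg.mixup import circular_hue_blend, full_mixup
from nucseg.pseudolabels import cluster_pixels, extract_padded_sample, select_label_patches


def first_sample(quality, seed):
    image, _ = generate_synthetic_slide(
        SyntheticSpec(n_nuclei=50, stain_quality=quality, seed=seed), 256, 256
    )
    sub = image[:128, :128]
    tissue = cluster_pixels(sub, seed=seed)
    patches = select_label_patches(tissue, 48)
    return extract_padded_sample(sub, patches[0])


a = first_sample("high", 1)  # saturated stain
b = first_sample("low", 2)   # pale stain
mixed = full_mixup(a, b, lam=0.5)

print(f"source labels: {a.label.sum()} and {b.label.sum()} nucleus pixels")
print(f"mixed label (pixelwise OR): {mixed.label.sum()} nucleus pixels")
print(f"hue 350 deg blended with 10 deg at lambda=0.5: "
      f"{circular_hue_blend(350.0, 10.0, 0.5):.0f} deg (not 180)")
print(
    "\nThe mixed patch shows both stain intensities at once while keeping "
    "every nucleus labeled - the augmentation that teaches the model to "
    "detect weakly stained nuclei."
)
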