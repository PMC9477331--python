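"""Unsupervised construction of training samples from raw HE images.

The pipeline needs no manual annotation: nuclei stand out from cytoplasm and
extra-cellular space (ECS) by color alone, so a 3-class k-means over pixel RGB
values yields a tissue map, and binary nucleus pseudo-labels are cut from it.

Training units are *asymmetric*: an ``N x N`` label patch is paired with the
``2N x 2N`` image crop centered on it (padding of N/2 on every side).  The
network is supervised only on the central region, which enlarges the effective
receptive field around the labeled area — a cheap form of spatial attention.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "TissueClass",
    "TissueMap",
    "LabelPatch",
    "SamplePatch",
    "extract_subgraphs",
    "cluster_pixels",
    "assign_tissue_classes",
    "select_label_patches",
    "extract_padded_sample",
]


class TissueClass(enum.IntEnum):
    NUCLEI = 0
    CYTOPLASM = 1
    ECS = 2


@dataclasses.dataclass(frozen=True)
class TissueMap:
    """3-class pixel map with the RGB centroid of each class.

    ``classes`` holds :class:`TissueClass` values; ``centroids`` is a (3, 3)
    array of RGB centroids in [0, 1], row-indexed by TissueClass.
    """

    classes: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        if self.centroids.shape != (3, 3):
            raise ValueError(f"expected 3 RGB centroids, got {self.centroids.shape}")

    @property
    def nuclei_mask(self) -> np.ndarray:
        return self.classes == TissueClass.NUCLEI


@dataclasses.dataclass(frozen=True)
class LabelPatch:
    """An eligible N x N binary nucleus label cut from a tissue map."""

    mask: np.ndarray        # N x N bool
    origin: Tuple[int, int]  # (row, col) of the patch in subgraph coordinates
    size: int

    def __post_init__(self) -> None:
        if self.mask.shape != (self.size, self.size):
            raise ValueError(
                f"label mask shape {self.mask.shape} does not match size {self.size}"
            )


@dataclasses.dataclass
class SamplePatch:
    """Asymmetric training unit: 2N x 2N image with its central N x N label."""

    image: np.ndarray   # 2N x 2N x 3, uint8 (raw) or float in [0,1] (mixed)
    label: np.ndarray   # N x N bool
    provenance: str = ""
    mixed: bool = False

    def __post_init__(self) -> None:
        n = self.label.shape[0]
        if self.label.shape != (n, n):
            raise ValueError(f"label must be square, got {self.label.shape}")
        if self.image.shape[:2] != (2 * n, 2 * n):
            raise ValueError(
                f"image side must be exactly twice the label side: "
                f"image {self.image.shape[:2]}, label {self.label.shape}"
            )

    @property
    def label_size(self) -> int:
        return self.label.shape[0]


def extract_subgraphs(
    image: np.ndarray, count: int, size: int, seed: int
) -> List[np.ndarray]:
    """Crop ``count`` random ``size x size`` sub-graphs (possibly overlapping)."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if size > h or size > w:
        raise ValueError(f"subgraph size {size} exceeds image dimensions {h}x{w}")
    rng = np.random.default_rng(seed)
    crops = []
    for _ in range(count):
        r = int(rng.integers(0, h - size + 1))
        c = int(rng.integers(0, w - size + 1))
        crops.append(image[r : r + size, c : c + size].copy())
    return crops


def cluster_pixels(subgraph: np.ndarray, k: int = 3, seed: int = 0) -> TissueMap:
    """K-means over per-pixel RGB (normalized to [0,1]), then name the classes.

    Raises a degeneracy error when the subgraph holds fewer distinct colors
    than ``k`` — clustering cannot produce k distinct centroids then.
    """
    subgraph = np.asarray(subgraph)
    if subgraph.ndim != 3 or subgraph.shape[2] != 3:
        raise ValueError(f"subgraph must be H x W x 3, got {subgraph.shape}")
    h, w = subgraph.shape[:2]
    pixels = subgraph.reshape(-1, 3).astype(np.float64) / 255.0
    n_distinct = np.unique(pixels, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"clustering degeneracy: subgraph has {n_distinct} distinct colors, "
            f"fewer than k={k}"
        )
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    raw = km.fit_predict(pixels).reshape(h, w)
    return assign_tissue_classes(raw, km.cluster_centers_)


# Minimum blue-minus-red margin (in [0,1] units) below which the nuclei vs
# cytoplasm decision is considered fragile and a warning is emitted.
BLUE_RED_MARGIN_FLOOR = 0.02


def assign_tissue_classes(raw_clusters: np.ndarray, centroids: np.ndarray) -> TissueMap:
    """Name three anonymous clusters by HE staining chemistry.

    ECS is the brightest centroid (unstained, near-white); of the remaining
    two, the one with the larger blue-minus-red difference is NUCLEI
    (hematoxylin is blue-purple), the other CYTOPLASM (eosin is pink).  Ties
    are broken deterministically by centroid index.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.shape != (3, 3):
        raise ValueError(f"expected exactly 3 RGB centroids, got {centroids.shape}")
    brightness = centroids.mean(axis=1)
    # argmax with index tie-break: numpy argmax already takes the first max
    ecs = int(np.argmax(brightness))
    rest = [i for i in range(3) if i != ecs]
    blue_minus_red = centroids[:, 2] - centroids[:, 0]
    if blue_minus_red[rest[0]] >= blue_minus_red[rest[1]]:
        nuclei, cyto = rest[0], rest[1]
    else:
        nuclei, cyto = rest[1], rest[0]
    margin = abs(blue_minus_red[nuclei] - blue_minus_red[cyto])
    if margin < BLUE_RED_MARGIN_FLOOR:
        warnings.warn(
            f"nuclei/cytoplasm blue-red margin {margin:.4f} below "
            f"{BLUE_RED_MARGIN_FLOOR}; class assignment may be unreliable"
        )
    mapping = np.empty(3, dtype=np.int32)
    mapping[nuclei] = TissueClass.NUCLEI
    mapping[cyto] = TissueClass.CYTOPLASM
    mapping[ecs] = TissueClass.ECS
    classes = mapping[np.asarray(raw_clusters)]
    ordered = np.empty((3, 3), dtype=np.float64)
    ordered[TissueClass.NUCLEI] = centroids[nuclei]
    ordered[TissueClass.CYTOPLASM] = centroids[cyto]
    ordered[TissueClass.ECS] = centroids[ecs]
    return TissueMap(classes=classes, centroids=ordered)


def select_label_patches(
    tissue: TissueMap,
    n: int,
    min_frac: float = 0.05,
    max_frac: float = 0.80,
) -> List[LabelPatch]:
    """Scan a stride-N/2 grid and keep patches with an eligible nucleus load.

    Positions leave an N/2 margin on every side so the padded 2N x 2N sample
    around each patch stays inside the subgraph.  A patch is eligible when its
    nucleus-pixel fraction lies in ``[min_frac, max_frac]`` — excluding both
    near-empty and nucleus-saturated regions.
    """
    if n % 2 != 0:
        raise ValueError(f"label size N must be even, got {n}")
    h, w = tissue.classes.shape
    if h < 2 * n or w < 2 * n:
        raise ValueError(f"tissue map {h}x{w} smaller than 2N={2 * n}")
    half = n // 2
    nuclei = tissue.nuclei_mask
    patches = []
    for r in range(half, h - half - n + 1, half):
        for c in range(half, w - half - n + 1, half):
            window = nuclei[r : r + n, c : c + n]
            frac = float(window.mean())
            if min_frac <= frac <= max_frac:
                patches.append(LabelPatch(mask=window.copy(), origin=(r, c), size=n))
    return patches


def extract_padded_sample(
    subgraph: np.ndarray, patch: LabelPatch, provenance: str = ""
) -> SamplePatch:
    """Cut the 2N x 2N image crop centered on a label patch (N/2 padding)."""
    n = patch.size
    half = n // 2
    r, c = patch.origin
    h, w = subgraph.shape[:2]
    if r < half or c < half or r + n + half > h or c + n + half > w:
        raise ValueError(
            f"patch at origin {patch.origin} with size {n} lacks the N/2 margin "
            f"inside a {h}x{w} subgraph"
        )
    image = subgraph[r - half : r + n + half, c - half : c + n + half].copy()
    return SamplePatch(image=image, label=patch.mask.astype(bool), provenance=provenance)
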