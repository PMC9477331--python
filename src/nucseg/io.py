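"""Raster I/O for the pipeline: 8-bit RGB images and 16-bit instance masks.

Images are PNG or TIFF, 8-bit, exactly three channels.  Instance masks are
single-channel 16-bit PNG/TIFF (supporting several hundred nuclei per tile).
All round trips are lossless; violations of the format contract raise
:class:`FormatError` naming the offending property.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_manifest",
    "read_manifest",
]


class FormatError(ValueError):
    """A raster file or array violates the pipeline's format contract."""


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image; reject anything that is not H x W x 3 uint8."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3 channels (RGB), got array of shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit pixels, got dtype {arr.dtype}")
    return np.asarray(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"image must be H x W x 3, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise FormatError(f"image must be uint8, got dtype {image.dtype}")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if _is_tiff(path):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 16-bit single-channel instance label map as int32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: instance mask must be single-channel, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: instance mask must hold integer labels, got dtype {arr.dtype}"
        )
    return arr.astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise FormatError(f"mask must be integer-typed, got dtype {mask.dtype}")
    if mask.size and (mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max):
        raise FormatError(
            f"mask labels must fit 16-bit unsigned range, got [{mask.min()}, {mask.max()}]"
        )
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = mask.astype(np.uint16)
    if _is_tiff(path):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_manifest(path: str | Path, entries: Iterable[Mapping]) -> None:
    """Write a dataset manifest: a JSON list of image/mask/split records."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(list(entries), fh, indent=2)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise FormatError(f"{path}: manifest must be a JSON list")
    return entries
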