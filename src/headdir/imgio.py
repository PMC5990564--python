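"""Image file I/O: 8-bit JPEG/PNG/TIFF frames as (H, W, 3) uint8 arrays."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

FRAME_EXTENSIONS = (".jpg", ".jpeg", ".png", ".tif", ".tiff")


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as RGB uint8; single-channel inputs are replicated to 3."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB") if im.mode != "RGB" else im)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return np.ascontiguousarray(arr, dtype=np.uint8)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    arr = np.asarray(pixels, dtype=np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    Image.fromarray(arr).save(path)
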