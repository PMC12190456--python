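"""Small raster helpers shared by the pipelines."""

from __future__ import annotations

import numpy as np
from PIL import Image


def resize_image(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an H x W x 3 uint8 raster to (height, width)."""
    h, w = size
    if image.shape[:2] == (h, w):
        return image
    return np.asarray(Image.fromarray(image).resize((w, h), Image.BILINEAR))


def bt601_luma(image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma: round(0.299 R + 0.587 G + 0.114 B), uint8."""
    rgb = image.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)
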