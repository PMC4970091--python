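"""Per-pixel color features over five common color spaces.

Each pixel is described by 15 components drawn from RGB, HSV, CIELAB,
CIELUV and YCbCr.  RGB channels are plain channels scaled to [0, 1]
(not chromatic coordinates); hue is reported in degrees in [0, 360) and
defined as 0 for achromatic pixels; CIELAB/CIELUV use the sRGB transfer
function with the D65 white point; YCbCr is full-range ITU-R BT.601
scaled to [0, 1].
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv, rgb2lab, rgb2luv

FEATURE_NAMES = (
    "r", "g", "b",
    "H", "S", "V",
    "L_lab", "a_lab", "b_lab",
    "L_luv", "u_luv", "v_luv",
    "Y", "Cb", "Cr",
)

N_FEATURES = len(FEATURE_NAMES)


def image_color_features(image: np.ndarray) -> np.ndarray:
    """Compute the 15 color features for every pixel of an 8-bit RGB image.

    Parameters
    ----------
    image : (H, W, 3) uint8 array

    Returns
    -------
    (H, W, 15) float64 array, feature order as in :data:`FEATURE_NAMES`.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    rgb = image.astype(np.float64) / 255.0

    hsv = rgb2hsv(rgb)
    hsv[..., 0] *= 360.0  # skimage hue is [0, 1)
    lab = rgb2lab(rgb)
    luv = rgb2luv(rgb)

    # Full-range BT.601 luma/chroma on [0, 1].
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    cb = (rgb[..., 2] - y) / 1.772 + 0.5
    cr = (rgb[..., 0] - y) / 1.402 + 0.5
    ycbcr = np.stack([y, cb, cr], axis=-1)

    return np.concatenate([rgb, hsv, lab, luv, ycbcr], axis=-1)


def compute_color_features(pixel) -> np.ndarray:
    """15-component feature vector for a single 8-bit RGB pixel.

    ``pixel`` is an (R, G, B) triple with channel values in [0, 255].
    """
    r, g, b = pixel
    for c in (r, g, b):
        if not (0 <= c <= 255):
            raise ValueError(f"channel value {c!r} outside [0, 255]")
    img = np.array([[[r, g, b]]], dtype=np.uint8)
    return image_color_features(img)[0, 0]
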