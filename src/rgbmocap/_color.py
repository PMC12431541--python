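"""HSL <-> RGB conversion on byte scales.

Hue, saturation and lightness are all expressed on a 0-255 scale (hue maps
the 360-degree circle onto 256 steps), matching how the marker colour ranges
are specified.  Conversion follows the standard HSL model.
"""

from __future__ import annotations

import numpy as np


def hsl_to_rgb(h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Convert HSL (each 0-255, any shape) to float RGB in [0, 255].

    Returns an array of shape ``(*shape, 3)``.
    """
    h = np.asarray(h, dtype=float) / 256.0  # hue fraction of the circle
    s = np.asarray(s, dtype=float) / 255.0
    l = np.asarray(l, dtype=float) / 255.0
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = (h % 1.0) * 6.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    seg = np.floor(hp).astype(int) % 6
    r1 = np.select([seg == 0, seg == 1, seg == 2, seg == 3, seg == 4, seg == 5],
                   [c, x, z, z, x, c])
    g1 = np.select([seg == 0, seg == 1, seg == 2, seg == 3, seg == 4, seg == 5],
                   [x, c, c, x, z, z])
    b1 = np.select([seg == 0, seg == 1, seg == 2, seg == 3, seg == 4, seg == 5],
                   [z, z, x, c, c, x])
    m = l - c / 2.0
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    return rgb * 255.0


def hsl_to_rgb_u8(h, s, l) -> np.ndarray:
    """Scalar/array HSL to uint8 RGB (rounded)."""
    return np.clip(np.round(hsl_to_rgb(h, s, l)), 0, 255).astype(np.uint8)


def hsl_in_range_mask(
    rgb: np.ndarray,
    h_range: tuple[float, float],
    s_range: tuple[float, float],
    l_range: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of pixels whose HSL falls inside all three closed ranges.

    Equivalent to thresholding :func:`rgb_to_hsl`, but the hue (the costly
    channel) is only evaluated on pixels that already pass the lightness and
    saturation gates, which makes this practical on full video frames.
    """
    x = np.asarray(rgb, dtype=np.float32) / np.float32(255.0)
    maxc = x.max(axis=-1)
    minc = x.min(axis=-1)
    l = (maxc + minc) * np.float32(0.5)
    d = maxc - minc
    mask = (l * 255.0 >= l_range[0]) & (l * 255.0 <= l_range[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(d == 0, np.float32(0), d / (1 - np.abs(2 * l - 1)))
    mask &= (s * 255.0 >= s_range[0]) & (s * 255.0 <= s_range[1])
    if not mask.any():
        return mask
    idx = np.nonzero(mask)
    sub = x[idx]
    h = rgb_to_hsl(sub * 255.0)[..., 0]
    ok = (h >= h_range[0]) & (h <= h_range[1])
    out = np.zeros_like(mask)
    out[idx] = ok
    return out


def rgb_to_hsl(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB (uint8 or float in [0, 255], shape (..., 3)) to HSL 0-255.

    Hue of achromatic pixels is 0.
    """
    rgb = np.asarray(rgb, dtype=float) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.max(rgb, axis=-1)
    minc = np.min(rgb, axis=-1)
    l = (maxc + minc) / 2.0
    d = maxc - minc
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(d == 0, 0.0, d / (1.0 - np.abs(2.0 * l - 1.0)))
        hr = np.where(d == 0, 0.0, ((g - b) / np.where(d == 0, 1.0, d)) % 6.0)
        hg = np.where(d == 0, 0.0, (b - r) / np.where(d == 0, 1.0, d) + 2.0)
        hb = np.where(d == 0, 0.0, (r - g) / np.where(d == 0, 1.0, d) + 4.0)
    hp = np.select([maxc == r, maxc == g], [hr, hg], default=hb)
    hp = np.where(d == 0, 0.0, hp)
    h = (hp / 6.0) % 1.0
    return np.stack([h * 256.0, np.clip(s, 0, 1) * 255.0, l * 255.0], axis=-1)
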