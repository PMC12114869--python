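"""Low-level color and mask operators used by the stigma segmentation pipeline.

Raster conventions
------------------
* RGB images are ``H x W x 3`` uint8 arrays, channel order red/green/blue.
* CIELAB images are ``H x W x 3`` float64 arrays in the 8-bit encoding used by
  most image libraries: ``L = L* * 255/100``, ``a = a* + 128``, ``b = b* + 128``.
  Values are kept as floats (no quantization) so colorimetric anchors stay exact.
* CMYK images are ``H x W x 4`` float64 arrays with each channel in [0, 255].
* Grayscale images are ``H x W`` numeric arrays in [0, 255].
* Binary masks are ``H x W`` uint8 arrays restricted to {0, 255}
  (0 = background, 255 = foreground).
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from scipy import ndimage
from skimage import color as _skcolor

FG = 255
BG = 0

__all__ = [
    "rgb_to_lab",
    "lab_decode",
    "rgb_to_cmyk",
    "max_rgb",
    "binary_threshold",
    "adaptive_threshold_gaussian",
    "morphology",
    "median_blur",
    "mask_logic",
    "mask_invert",
    "min_enclosing_circle_mask",
    "crop_to_bounding_rect",
]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    return img


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected HxW binary mask, got shape {mask.shape}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (BG, FG))):
        raise TypeError(f"mask is not binary over {{0, 255}}: values {vals[:8]}")
    return mask.astype(np.uint8)


def _check_odd(k: int, name: str) -> int:
    k = int(k)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"{name} must be an odd positive integer, got {k}")
    return k


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an sRGB image to CIELAB in the 8-bit-scaled encoding.

    Uses the D65 standard illuminant.  L* in [0, 100] is rescaled by 255/100;
    a* and b* are offset by +128 so that 128 encodes 0.  The result is float64
    and unquantized: pure black maps to exactly (0, 128, 128) and pure white
    to (255, ~128, ~128).
    """
    img = _check_rgb(img)
    lab = _skcolor.rgb2lab(img.astype(np.uint8))
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * (255.0 / 100.0)
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return out


def lab_decode(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Undo the 8-bit-scaled encoding, returning (L*, a*, b*) float planes."""
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected HxWx3 Lab image, got shape {lab.shape}")
    return lab[..., 0] * (100.0 / 255.0), lab[..., 1] - 128.0, lab[..., 2] - 128.0


def rgb_to_cmyk(img: np.ndarray) -> np.ndarray:
    """Naive device CMYK conversion on the 0-255 scale.

    K = 255 - max(R, G, B); C, M, Y = 255 * (1 - c' - k') / (1 - k') with
    c', k' the unit-scaled channel and key, and C = M = Y = 0 where K = 255.
    CMYK has no colorimetric standard; this max-based form is the common
    device conversion.
    """
    img = _check_rgb(img).astype(float)
    mx = img.max(axis=2)
    k = 255.0 - mx
    out = np.zeros(img.shape[:2] + (4,), dtype=float)
    safe = mx > 0
    denom = np.where(safe, mx, 1.0)
    for i in range(3):
        out[..., i] = np.where(safe, 255.0 * (mx - img[..., i]) / denom, 0.0)
    out[..., 3] = k
    return out


def max_rgb(img: np.ndarray, mode: str = "rescale") -> np.ndarray:
    """Max-RGB white balance.

    mode="rescale" (default): each channel is globally rescaled so its
    image-wide maximum becomes 255 (white-patch assumption per channel).
    mode="perpixel": each pixel is normalized by its own maximum channel.
    An all-zero channel is left unchanged with a warning.
    """
    img = _check_rgb(img).astype(float)
    out = np.empty_like(img)
    if mode == "rescale":
        for i in range(3):
            m = img[..., i].max()
            if m == 0:
                warnings.warn(f"max_rgb: channel {i} is all zero; left unchanged")
                out[..., i] = img[..., i]
            else:
                out[..., i] = img[..., i] * (255.0 / m)
    elif mode == "perpixel":
        mx = img.max(axis=2)
        if (mx == 0).all():
            warnings.warn("max_rgb: image is all zero; left unchanged")
            return img.astype(np.uint8)
        denom = np.where(mx > 0, mx, 1.0)
        out = img * (255.0 / denom)[..., None]
    else:
        raise ValueError(f"unknown max_rgb mode {mode!r}")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binary_threshold(img: np.ndarray, cutoff: float, above_is_fg: bool = True) -> np.ndarray:
    """Global threshold: pixel > cutoff maps to foreground (or inverted)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected HxW grayscale image, got shape {img.shape}")
    if not 0 <= cutoff <= 255:
        raise ValueError(f"cutoff must be in [0, 255], got {cutoff}")
    fg = img > cutoff
    if not above_is_fg:
        fg = ~fg
    return np.where(fg, FG, BG).astype(np.uint8)


def _gaussian_kernel1d(ksize: int) -> np.ndarray:
    # OpenCV getGaussianKernel convention: sigma = 0.3*((ksize-1)*0.5 - 1) + 0.8
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def adaptive_threshold_gaussian(
    img: np.ndarray, neighborhood: int = 11, offset: float = 2.0
) -> np.ndarray:
    """Adaptive threshold against a Gaussian-weighted local mean.

    A pixel is foreground iff its value exceeds the Gaussian-weighted mean of
    its ``neighborhood x neighborhood`` window minus ``offset``.  Borders are
    handled by reflection.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected HxW grayscale image, got shape {img.shape}")
    neighborhood = _check_odd(neighborhood, "neighborhood")
    if neighborhood < 3:
        raise ValueError("neighborhood must be >= 3")
    k1 = _gaussian_kernel1d(neighborhood)
    local = ndimage.correlate1d(img, k1, axis=0, mode="reflect")
    local = ndimage.correlate1d(local, k1, axis=1, mode="reflect")
    return np.where(img > local - offset, FG, BG).astype(np.uint8)


def morphology(mask: np.ndarray, op: str, kernel: int) -> np.ndarray:
    """Binary morphology with a k x k all-ones structuring element.

    ``close`` is erode(dilate(.)) and ``open`` is dilate(erode(.)) by
    definition.  Erosion treats pixels beyond the border as foreground and
    dilation as background, so blobs touching the frame are not eaten away.
    """
    mask = _check_mask(mask)
    k = _check_odd(kernel, "kernel")
    m = mask.astype(bool)

    # A square all-ones SE is separable: dilation = 2-D running maximum,
    # erosion = running minimum.  Constant padding (0 for dilation, 1 for
    # erosion) keeps blobs touching the frame intact.
    def dil(x):
        return ndimage.maximum_filter(x, size=k, mode="constant", cval=0)

    def ero(x):
        return ndimage.minimum_filter(x, size=k, mode="constant", cval=1)

    if op == "dilate":
        m = dil(m)
    elif op == "erode":
        m = ero(m)
    elif op == "open":
        m = dil(ero(m))
    elif op == "close":
        m = ero(dil(m))
    else:
        raise ValueError(f"unknown morphology op {op!r}")
    return np.where(m, FG, BG).astype(np.uint8)


def median_blur(img: np.ndarray, aperture: int) -> np.ndarray:
    """Square-window median filter with reflected borders."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected HxW grayscale image, got shape {img.shape}")
    aperture = _check_odd(aperture, "aperture")
    return ndimage.median_filter(img, size=aperture, mode="reflect")


def mask_logic(a: np.ndarray, b: np.ndarray, op: str) -> np.ndarray:
    """Pixel-wise boolean algebra on {0, 255} masks."""
    a = _check_mask(a)
    b = _check_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    if op == "and":
        out = a.astype(bool) & b.astype(bool)
    elif op == "or":
        out = a.astype(bool) | b.astype(bool)
    elif op == "xor":
        out = a.astype(bool) ^ b.astype(bool)
    else:
        raise ValueError(f"unknown mask op {op!r}")
    return np.where(out, FG, BG).astype(np.uint8)


def mask_invert(a: np.ndarray) -> np.ndarray:
    a = _check_mask(a)
    return (FG - a).astype(np.uint8)


def min_enclosing_circle_mask(mask: np.ndarray) -> np.ndarray:
    """Filled disc of the minimum circle enclosing all foreground pixels.

    Pixel centers are taken at integer coordinates; a pixel belongs to the
    disc if its center lies within the circle (plus a small epsilon so that
    boundary-defining pixels are always included).
    """
    mask = _check_mask(mask)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask: no foreground pixels to enclose")
    coords = np.column_stack([cc, rr]).astype(float)
    if coords.shape[0] > 500:
        # the enclosing circle depends only on the convex hull vertices
        from scipy.spatial import ConvexHull

        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:
            pass  # degenerate (collinear) point sets fall through to shapely
    pts = shapely.MultiPoint(coords)
    circle = shapely.minimum_bounding_circle(pts)
    minx, miny, maxx, maxy = circle.bounds
    center = np.array([(miny + maxy) / 2.0, (minx + maxx) / 2.0])  # (row, col)
    radius = (maxx - minx) / 2.0
    r_idx, c_idx = np.indices(mask.shape)
    d2 = (r_idx - center[0]) ** 2 + (c_idx - center[1]) ** 2
    return np.where(d2 <= (radius + 1e-6) ** 2, FG, BG).astype(np.uint8)


def crop_to_bounding_rect(
    img: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Crop image and mask to the tight bounding box of the mask foreground.

    Returns (cropped_img, cropped_mask, (row_offset, col_offset)) so that
    cropped coordinates map back as original = cropped + offset.
    """
    mask = _check_mask(mask)
    img = np.asarray(img)
    if img.shape[:2] != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape[:2]} vs {mask.shape}")
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask: nothing to crop to")
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    return img[r0:r1, c0:c1], mask[r0:r1, c0:c1], (r0, c0)
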