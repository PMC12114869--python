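"""Two-phase stigma segmentation for axial cannabis inflorescence photographs.

Phase 1 isolates the inflorescence from the dark background (CIELAB L-channel
threshold, opening, dilation, minimum enclosing circle, bounding-box crop).
Phase 2 isolates the stigma filaments inside the crop by combining an
adaptively thresholded, median-blurred K-channel with a blue-channel gate on
a max-RGB white-balanced copy, then rescuing large bright stigmas through an
inverted K-channel threshold.

All numeric constants live in :class:`PipelineConfig`; defaults are tuned for
evenly lit copy-stand photographs of a single inflorescence on a dark
background.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import color as ce


class SegmentationError(RuntimeError):
    """Raised when a pipeline phase cannot produce a usable mask."""

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"[{step}] {message}")


@dataclass
class PipelineConfig:
    """Numeric constants of the segmentation operator chain.

    All thresholds are on the 0-255 scale (the L-channel is CIE L* rescaled
    by 255/100); all kernels are odd square sizes in pixels.
    """

    l_threshold: int = 41
    open_kernel: int = 27
    dilate_kernel: int = 41
    k_median: int = 11
    adaptive_window: int = 11
    adaptive_offset: float = 2.0
    b_threshold: int = 111
    close_kernel: int = 5
    k_threshold: int = 110
    maxrgb_mode: str = "rescale"
    caption_variant: bool = False  # use the figure-caption AND->OR ordering

    def __post_init__(self) -> None:
        for name in ("open_kernel", "dilate_kernel", "k_median", "adaptive_window", "close_kernel"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {v}")
        for name in ("l_threshold", "b_threshold", "k_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    """Output bundle of the full pipeline.

    ``intermediates`` holds the named masks/images in operator order for QC
    rendering; ``qc`` carries foreground pixel counts and the stigma fraction.
    """

    stigma_mask: np.ndarray
    cropped_rgb: np.ndarray
    inflorescence_mask: np.ndarray
    offset: tuple[int, int]
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)
    qc: dict[str, float] = field(default_factory=dict)


class StigmaSegmenter(BaseEstimator):
    """Stateless image-to-mask transformer implementing the operator chain.

    Parameters mirror :class:`PipelineConfig`.  ``fit`` is a no-op (the
    pipeline has no trainable state); ``transform`` maps a list of RGB images
    to a list of :class:`SegmentationResult`.
    """

    def __init__(
        self,
        l_threshold: int = 41,
        open_kernel: int = 27,
        dilate_kernel: int = 41,
        k_median: int = 11,
        adaptive_window: int = 11,
        adaptive_offset: float = 2.0,
        b_threshold: int = 111,
        close_kernel: int = 5,
        k_threshold: int = 110,
        maxrgb_mode: str = "rescale",
        caption_variant: bool = False,
    ):
        self.l_threshold = l_threshold
        self.open_kernel = open_kernel
        self.dilate_kernel = dilate_kernel
        self.k_median = k_median
        self.adaptive_window = adaptive_window
        self.adaptive_offset = adaptive_offset
        self.b_threshold = b_threshold
        self.close_kernel = close_kernel
        self.k_threshold = k_threshold
        self.maxrgb_mode = maxrgb_mode
        self.caption_variant = caption_variant

    def _config(self) -> PipelineConfig:
        return PipelineConfig(**self.get_params())

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [run_pipeline(img, self._config()) for img in X]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def isolate_inflorescence(
    img: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[int, int], dict[str, np.ndarray]]:
    """Phase 1: separate the inflorescence from the dark background.

    Returns (cropped_rgb, cropped_circle_mask, offset, intermediates).  Pixels
    outside the minimum enclosing circle are replaced with black so that no
    background detail leaks into the color analysis.
    """
    cfg = cfg or PipelineConfig()
    lab = ce.rgb_to_lab(img)
    l_chan = lab[..., 0]
    l_mask = ce.binary_threshold(l_chan, cfg.l_threshold)
    if not l_mask.any():
        raise SegmentationError(
            "l_threshold", f"no inflorescence found: no pixel above L-threshold {cfg.l_threshold}"
        )
    opened = ce.morphology(l_mask, "open", cfg.open_kernel)
    if not opened.any():
        raise SegmentationError(
            "opening", f"no inflorescence found: {cfg.open_kernel}x{cfg.open_kernel} opening removed all foreground"
        )
    dilated = ce.morphology(opened, "dilate", cfg.dilate_kernel)
    circle = ce.min_enclosing_circle_mask(dilated)
    masked_rgb = np.where(circle[..., None] == ce.FG, img, 0).astype(np.uint8)
    cropped_rgb, cropped_circle, offset = ce.crop_to_bounding_rect(masked_rgb, circle)
    intermediates = {
        "lab": lab,
        "l_mask": l_mask,
        "opened": opened,
        "dilated": dilated,
        "circle": circle,
        "masked_rgb": masked_rgb,
    }
    return cropped_rgb, cropped_circle, offset, intermediates


def isolate_stigmas(
    cropped: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Phase 2: isolate stigma filaments within the cropped inflorescence.

    May legitimately return an empty mask (no stigmas detected); callers see
    this via the QC stigma fraction rather than an exception.
    """
    cfg = cfg or PipelineConfig()
    if cropped.size == 0:
        raise SegmentationError("crop", "empty cropped image")

    cmyk = ce.rgb_to_cmyk(cropped)
    k_blur = ce.median_blur(cmyk[..., 3], cfg.k_median)
    adaptive = ce.adaptive_threshold_gaussian(k_blur, cfg.adaptive_window, cfg.adaptive_offset)

    balanced = ce.max_rgb(cropped, mode=cfg.maxrgb_mode)
    b_mask = ce.binary_threshold(balanced[..., 2].astype(float), cfg.b_threshold)

    combined = ce.mask_logic(b_mask, adaptive, "and")
    closed = ce.morphology(combined, "close", cfg.close_kernel)

    # Large-stigma rescue branch: bright pixels have low K.
    k_gate = ce.binary_threshold(cmyk[..., 3], cfg.k_threshold)
    k_rescue = ce.mask_invert(k_gate)

    if cfg.caption_variant:
        final = ce.mask_logic(closed, k_rescue, "or")
        xored = closed
    else:
        xored = ce.mask_logic(closed, b_mask, "xor")
        final = ce.mask_logic(xored, k_rescue, "or")

    intermediates = {
        "cmyk_k": cmyk[..., 3],
        "k_blur": k_blur,
        "adaptive": adaptive,
        "maxrgb": balanced,
        "b_mask": b_mask,
        "and_mask": combined,
        "closed": closed,
        "xor_mask": xored,
        "k_rescue": k_rescue,
        "final": final,
    }
    return final, intermediates


def run_pipeline(img: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Full pipeline: inflorescence isolation followed by stigma isolation.

    The stigma mask is intersected with the inflorescence circle so that the
    blacked-out surround never contributes to stigma statistics.
    """
    cfg = cfg or PipelineConfig()
    h, w = np.asarray(img).shape[:2]
    largest = max(cfg.open_kernel, cfg.dilate_kernel)
    if min(h, w) < largest:
        raise SegmentationError(
            "input", f"image too small: {h}x{w} is below the largest kernel {largest}"
        )
    cropped_rgb, circle_mask, offset, inter1 = isolate_inflorescence(img, cfg)
    stigma_raw, inter2 = isolate_stigmas(cropped_rgb, cfg)
    stigma_mask = ce.mask_logic(stigma_raw, circle_mask, "and")

    n_inflo = int((circle_mask == ce.FG).sum())
    n_stigma = int((stigma_mask == ce.FG).sum())
    result = SegmentationResult(
        stigma_mask=stigma_mask,
        cropped_rgb=cropped_rgb,
        inflorescence_mask=circle_mask,
        offset=offset,
        intermediates={**inter1, **inter2},
        qc={
            "inflorescence_pixels": n_inflo,
            "stigma_pixels": n_stigma,
            "stigma_fraction": n_stigma / n_inflo if n_inflo else 0.0,
        },
    )
    return result
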