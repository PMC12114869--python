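"""Stigma yellowness ("amber score") quantification and maturity staging.

The amber score maps each stigma pixel onto the line segment joining two
CIELAB anchors — pure white (L* = 100, b* = 0) and saturated sRGB yellow —
via scalar projection, clamped to [0, 1] and scaled to [0, 100].  The white
anchor therefore scores exactly 0 and the yellow anchor exactly 100.  The
mean score over the stigma mask is the inflorescence's automated amber score,
and a nearest-center rule against the four stage reference scores assigns the
ordinal amber stage (1 fully white ... 4 fully amber).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import color as ce

def _anchor_lb(rgb: tuple[int, int, int]) -> tuple[float, float]:
    lab = ce.rgb_to_lab(np.array([[rgb]], dtype=np.uint8))
    return float(lab[0, 0, 0] * 100.0 / 255.0), float(lab[0, 0, 2] - 128.0)


#: CIELAB (L*, b*) coordinates of the index anchors: pure sRGB white
#: (nominally L* = 100, b* = 0) and saturated sRGB yellow (255, 255, 0) under
#: D65.  Both are computed with the same conversion used on image pixels so
#: that the anchors score exactly 0 and 100 by construction.
WHITE_ANCHOR_LB = _anchor_lb((255, 255, 255))
YELLOW_ANCHOR_LB = _anchor_lb((255, 255, 0))

#: Default stage reference scores: population means of the automated amber
#: score within each manually assessed stage.
DEFAULT_STAGE_CENTERS = (28.0, 37.0, 54.0, 65.0)

STAGE_LABELS = {1: "fully white", 2: "some amber", 3: "mostly amber", 4: "fully amber"}


@dataclass
class AmberResult:
    per_pixel: np.ndarray  # yellowness in [0, 100] over mask pixels
    mean_score: float
    n_pixels: int
    stage: int | None = None
    stage_label: str | None = None


def yellowness_index(lab: np.ndarray, mask: np.ndarray) -> AmberResult:
    """Per-pixel yellowness over a stigma mask, with its mean amber score.

    Parameters
    ----------
    lab : HxWx3 CIELAB image in the 8-bit-scaled encoding of
        :func:`amberscan.color.rgb_to_lab`.
    mask : HxW binary mask selecting stigma pixels.

    The index is ``100 * clamp(t, 0, 1)`` where ``t`` is the scalar projection
    of the pixel's (L*, b*) onto the white→yellow anchor segment.  Pixels with
    negative projection (e.g. bluish pixels with b* < 0) clamp to 0.
    """
    mask = np.asarray(mask)
    if lab.shape[:2] != mask.shape:
        raise ValueError(f"lab/mask shape mismatch: {lab.shape[:2]} vs {mask.shape}")
    sel = mask == ce.FG
    if not sel.any():
        raise ValueError("no stigma pixels: mask is empty")
    L, _, b = ce.lab_decode(lab)
    dl = YELLOW_ANCHOR_LB[0] - WHITE_ANCHOR_LB[0]
    db = YELLOW_ANCHOR_LB[1] - WHITE_ANCHOR_LB[1]
    norm2 = dl * dl + db * db
    t = ((L[sel] - WHITE_ANCHOR_LB[0]) * dl + (b[sel] - WHITE_ANCHOR_LB[1]) * db) / norm2
    per_pixel = 100.0 * np.clip(t, 0.0, 1.0)
    return AmberResult(
        per_pixel=per_pixel,
        mean_score=float(per_pixel.mean()),
        n_pixels=int(sel.sum()),
    )


def classify_stage(mean_score: float, centers=DEFAULT_STAGE_CENTERS) -> int:
    """Nearest-center amber stage (1-4); exact midpoint ties go to the lower stage."""
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (4,) or not np.all(np.diff(centers) > 0):
        raise ValueError(f"centers must be 4 strictly increasing values, got {centers}")
    if not 0.0 <= mean_score <= 100.0:
        raise ValueError(f"mean_score must be in [0, 100], got {mean_score}")
    d = np.abs(centers - mean_score)
    return int(np.argmin(d)) + 1  # argmin takes the first (lower) stage on ties


def score_image(lab: np.ndarray, mask: np.ndarray, centers=DEFAULT_STAGE_CENTERS) -> AmberResult:
    """Yellowness index plus stage assignment in one call."""
    res = yellowness_index(lab, mask)
    res.stage = classify_stage(res.mean_score, centers)
    res.stage_label = STAGE_LABELS[res.stage]
    return res


class AmberStageClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-center stage classifier over mean amber scores.

    With ``centers=None`` the per-stage mean scores are estimated from the
    training data at ``fit`` time; otherwise the supplied reference centers
    are used (the population defaults come from manual-vs-automated stage
    calibration).
    """

    def __init__(self, centers: tuple | None = DEFAULT_STAGE_CENTERS):
        self.centers = centers

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).reshape(-1)
        if self.centers is not None:
            centers = np.asarray(self.centers, dtype=float)
        else:
            if y is None:
                raise ValueError("y (manual stages) required when centers=None")
            y = np.asarray(y)
            centers = np.array([X[y == s].mean() for s in (1, 2, 3, 4)])
        if centers.shape != (4,) or not np.all(np.diff(centers) > 0):
            raise ValueError("stage centers must be 4 strictly increasing values")
        self.centers_ = centers
        self.classes_ = np.array([1, 2, 3, 4])
        return self

    def predict(self, X):
        if not hasattr(self, "centers_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        d = np.abs(X - self.centers_[None, :])
        return np.argmin(d, axis=1) + 1


def stage_summary(results) -> dict[int, dict[str, float]]:
    """Per-manual-stage mean and standard error of the automated amber score.

    ``results`` is an iterable of (manual_stage, mean_score) pairs.  The SE is
    sd/sqrt(n) with the n-1 denominator; a stage with fewer than two
    observations reports SE = nan (undefined, not zero).
    """
    by_stage: dict[int, list[float]] = {}
    for stage, score in results:
        by_stage.setdefault(int(stage), []).append(float(score))
    out: dict[int, dict[str, float]] = {}
    for stage in sorted(by_stage):
        vals = np.asarray(by_stage[stage])
        n = vals.size
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        out[stage] = {"mean": float(vals.mean()), "se": se, "n": n}
    return out
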