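"""Registration accuracy and image-quality metrics.

Accuracy is the target registration error (TRE): the mean Euclidean distance,
in pixels, between each fixed-image landmark and the transformed position of
its moving-image counterpart, over a set of expert (or synthetic ground
truth) correspondences — typically 10 per pair.  Success is TRE below 1 px
for super-resolution and below 5 px for mosaicking and longitudinal study,
evaluated at the native image resolution.

Image quality of a pair is summarized by MSE and SSIM between the images and
by the peak deviation nonuniformity UN = (I_max + I_min) / (I_max - I_min)
within the circular field-of-view ROI (higher UN = more uniform; the pair
value is the mean of the two images' UN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

logger = logging.getLogger(__name__)

#: returned for UN when the ROI is perfectly uniform (max == min)
UN_SENTINEL = 1.0e6

CATEGORY_THRESHOLDS = {
    "super_resolution": 1.0,
    "mosaicking": 5.0,
    "longitudinal": 5.0,
}
_CATEGORY_ALIASES = {"S": "super_resolution", "P": "mosaicking", "A": "longitudinal"}


@dataclass(frozen=True)
class LandmarkSet:
    """Corresponding landmark coordinates, fixed and moving, as (n, 2) (x, y)."""

    fixed: np.ndarray
    moving: np.ndarray

    def __post_init__(self):
        f = np.atleast_2d(np.asarray(self.fixed, dtype=np.float64))
        m = np.atleast_2d(np.asarray(self.moving, dtype=np.float64))
        if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 2 or len(f) < 1:
            raise ValueError("landmarks must be matching (n>=1, 2) arrays")
        if not (np.isfinite(f).all() and np.isfinite(m).all()):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "fixed", f)
        object.__setattr__(self, "moving", m)

    def __len__(self) -> int:
        return len(self.fixed)

    def scaled(self, factor: float) -> "LandmarkSet":
        """Rescale both frames (e.g. working -> native resolution)."""
        return LandmarkSet(self.fixed * factor, self.moving * factor)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "x_fixed": self.fixed[:, 0],
                "y_fixed": self.fixed[:, 1],
                "x_moving": self.moving[:, 0],
                "y_moving": self.moving[:, 1],
            }
        )
        with open(path, "w") as fh:
            fh.write("# 0-based pixel coordinates, native resolution\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path, comment="#")
        return cls(
            np.column_stack([df["x_fixed"], df["y_fixed"]]),
            np.column_stack([df["x_moving"], df["y_moving"]]),
        )


def tre(landmarks: LandmarkSet, transformation) -> float:
    """Mean Euclidean landmark distance after applying the moving->fixed map."""
    if len(landmarks) == 0:
        raise ValueError("empty landmark set")
    mapped = transformation.apply(landmarks.moving)
    return float(np.linalg.norm(mapped - landmarks.fixed, axis=1).mean())


def classify_success(tre_value: float, category: str) -> bool:
    """Strict below-threshold success rule per application category."""
    if tre_value < 0:
        raise ValueError("TRE must be non-negative")
    category = _CATEGORY_ALIASES.get(category, category)
    if category not in CATEGORY_THRESHOLDS:
        raise ValueError(f"unknown category {category!r}")
    return tre_value < CATEGORY_THRESHOLDS[category]


def estimate_fov_mask(img: np.ndarray) -> np.ndarray:
    """Circular field-of-view mask by Otsu thresholding of the dark frame."""
    img = np.asarray(img, dtype=np.float64)
    try:
        thr = threshold_otsu(img)
    except ValueError:  # constant image
        return np.ones_like(img, dtype=bool)
    mask = img > thr
    mask = ndimage.binary_fill_holes(mask)
    return mask


def peak_deviation_nonuniformity(img: np.ndarray, roi_mask: np.ndarray) -> float:
    """UN = (max + min) / (max - min) over the ROI; sentinel when uniform."""
    vals = np.asarray(img, dtype=np.float64)[roi_mask]
    hi, lo = float(vals.max()), float(vals.min())
    if hi - lo <= 0:
        logger.warning("uniform ROI: UN undefined, returning sentinel %g", UN_SENTINEL)
        return UN_SENTINEL
    return (hi + lo) / (hi - lo)


@dataclass(frozen=True)
class QualityMetrics:
    mse: float
    ssim: float
    un: float  # pair value: mean of the two images' UN


def image_quality(
    a: np.ndarray, b: np.ndarray, roi_mask: np.ndarray | None = None
) -> QualityMetrics:
    """MSE, SSIM and pair UN of two equally-sized [0, 1] gray images.

    MSE and the SSIM map are averaged over the ROI (the circular field of
    view, estimated from the first image when no mask is given).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape")
    if roi_mask is None:
        roi_mask = estimate_fov_mask(a)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    mse = float(((a - b) ** 2)[roi_mask].mean())
    _, ssim_map = structural_similarity(a, b, data_range=1.0, full=True)
    ssim = float(ssim_map[roi_mask].mean())
    un = 0.5 * (
        peak_deviation_nonuniformity(a, roi_mask)
        + peak_deviation_nonuniformity(b, roi_mask)
    )
    return QualityMetrics(mse=mse, ssim=ssim, un=un)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value (average ranks on ties).

    Constant input has no defined rank ordering; (nan, nan) is returned with
    a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
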