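"""HOG descriptors for saddle points and nearest-neighbor matching.

Each feature point is described by a histogram-of-oriented-gradients vector
computed on a 32x32 window of the grayscale working image centered at the
rounded point location: 8x8-pixel cells, 2x2-cell blocks with one-cell
stride, 9 unsigned orientation bins, L2 block normalization — 324 values.
Points near the border use reflect padding.

Matching is one-directional nearest neighbor in Euclidean distance with
Lowe's ratio test at threshold 0.9 (boundary inclusive).  Exact search is
used; at the few thousand descriptors a fundus image yields, approximate
search is purely an optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import hog

from .detector import FeaturePoint
from .image import validate_gray

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 32
DEFAULT_RATIO = 0.9
_HOG_KW = dict(
    orientations=9,
    pixels_per_cell=(8, 8),
    cells_per_block=(2, 2),
    block_norm="L2",
    feature_vector=True,
)


def descriptor_length(window: int = DEFAULT_WINDOW) -> int:
    cells = window // 8
    blocks = cells - 1
    return blocks * blocks * 4 * 9


@dataclass(frozen=True)
class Match:
    idx_fixed: int
    idx_moving: int
    ratio: float


def extract_hog(
    img: np.ndarray, point: FeaturePoint, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """HOG descriptor of the window centered at *point* (rounded to pixel)."""
    return extract_all(img, [point], window=window)[0]


def extract_all(
    img: np.ndarray, points: list[FeaturePoint], window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """(K, D) descriptor matrix for all points, in point order.

    The image is reflect-padded by half a window so border points get a full
    window; such points are logged.
    """
    img = validate_gray(img)
    half = window // 2
    padded = np.pad(img, half, mode="reflect")
    n, m = img.shape
    out = np.empty((len(points), descriptor_length(window)))
    n_border = 0
    for i, p in enumerate(points):
        cx = int(round(p.x))
        cy = int(round(p.y))
        if not (0 <= cx < m and 0 <= cy < n):
            raise ValueError(f"point ({p.x}, {p.y}) outside the {m}x{n} image")
        if cx < half or cy < half or cx >= m - half or cy >= n - half:
            n_border += 1
        win = padded[cy : cy + window, cx : cx + window]
        out[i] = hog(win, **_HOG_KW)
    if n_border:
        logger.info("%d/%d descriptor windows crossed the border (reflected)",
                    n_border, len(points))
    return out


def match_descriptors(
    desc_fixed: np.ndarray,
    desc_moving: np.ndarray,
    ratio_threshold: float = DEFAULT_RATIO,
) -> list[Match]:
    """One-directional ratio-test matching, fixed -> moving.

    For each fixed descriptor the nearest and second-nearest moving
    descriptors are found by Euclidean distance; the pair is kept iff
    d1/d2 <= ratio_threshold.  Symmetry is deliberately not enforced.
    """
    a = np.asarray(desc_fixed, dtype=np.float64)
    b = np.asarray(desc_moving, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or (a.size and b.size and a.shape[1] != b.shape[1]):
        raise ValueError("descriptor matrices must be 2D with equal width")
    if len(b) < 2:
        logger.warning("fewer than 2 moving descriptors; no ratio computable")
        return []
    matches: list[Match] = []
    bb = (b * b).sum(axis=1)
    block = max(1, int(2e7 // max(len(b), 1)))
    for start in range(0, len(a), block):
        chunk = a[start : start + block]
        d2 = (
            (chunk * chunk).sum(axis=1)[:, None]
            - 2.0 * chunk @ b.T
            + bb[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        order = np.argpartition(d2, 1, axis=1)[:, :2]
        for i in range(len(chunk)):
            j1, j2 = order[i]
            if d2[i, j1] > d2[i, j2]:
                j1, j2 = j2, j1
            d1 = float(np.sqrt(d2[i, j1]))
            dd2 = float(np.sqrt(d2[i, j2]))
            ratio = 0.0 if dd2 == 0.0 else d1 / dd2
            if ratio <= ratio_threshold:
                matches.append(Match(idx_fixed=start + i, idx_moving=int(j1), ratio=ratio))
    return matches
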