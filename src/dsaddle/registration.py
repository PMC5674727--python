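"""Robust transformation estimation and image warping.

After descriptor matching, outliers are rejected with MSAC (M-estimator
sample consensus): random minimal samples propose similarity hypotheses,
scored by the truncated squared reprojection error

    cost = sum_i min(r_i^2, max_distance^2).

The winning hypothesis' inliers (r <= max_distance) select the final model by
count — similarity (<= 8 inliers), affine (9..30), or full second-order
polynomial (> 30) — which is then fit to all inliers by least squares.
Because MSAC is randomized, the MSAC + fit round is repeated many times per
truncation distance (four distances by default) and the best round is kept:
by smallest landmark TRE when ground truth is available (the evaluation
protocol), otherwise by most inliers then smallest mean residual.

All transformations map moving-image coordinates to fixed-image coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .descriptor import DEFAULT_RATIO, Match, extract_all, match_descriptors
from .detector import DetectorConfig, detect, features_to_array
from .evaluation import LandmarkSet, tre
from .image import validate_gray

logger = logging.getLogger(__name__)

MODELS = ("similarity", "affine", "polynomial2")
_MIN_PAIRS = {"similarity": 2, "affine": 3, "polynomial2": 6}
_N_PARAMS = {"similarity": 4, "affine": 6, "polynomial2": 12}


def _poly2_basis(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass(frozen=True)
class Transformation:
    """A moving -> fixed coordinate map.

    Parameter layout:
      similarity:  [a, b, tx, ty]          x' = a x - b y + tx, y' = b x + a y + ty
      affine:      [a11, a12, a21, a22, tx, ty]
      polynomial2: 12 values, 6 per output coordinate on the basis
                   {1, x, y, x^2, xy, y^2}
    """

    model: str
    params: np.ndarray

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        p = np.asarray(self.params, dtype=np.float64)
        if p.shape != (_N_PARAMS[self.model],):
            raise ValueError(
                f"{self.model} expects {_N_PARAMS[self.model]} params, got {p.shape}"
            )
        if not np.isfinite(p).all():
            raise ValueError("transformation parameters must be finite")
        object.__setattr__(self, "params", p)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map an (K, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        p = self.params
        if self.model == "similarity":
            a, b, tx, ty = p
            x, y = pts[:, 0], pts[:, 1]
            return np.column_stack([a * x - b * y + tx, b * x + a * y + ty])
        if self.model == "affine":
            a11, a12, a21, a22, tx, ty = p
            x, y = pts[:, 0], pts[:, 1]
            return np.column_stack([a11 * x + a12 * y + tx, a21 * x + a22 * y + ty])
        basis = _poly2_basis(pts)
        return np.column_stack([basis @ p[:6], basis @ p[6:]])

    def inverse(self) -> "Transformation":
        """Exact inverse for similarity/affine; unavailable for polynomial2."""
        p = self.params
        if self.model == "similarity":
            a, b, tx, ty = p
            det = a * a + b * b
            if det == 0:
                raise ValueError("degenerate similarity (zero scale)")
            ai, bi = a / det, -b / det
            return Transformation(
                "similarity",
                [ai, bi, -(ai * tx - bi * ty), -(bi * tx + ai * ty)],
            )
        if self.model == "affine":
            m = np.array([[p[0], p[1]], [p[2], p[3]]])
            t = p[4:6]
            mi = np.linalg.inv(m)
            ti = -mi @ t
            return Transformation("affine", [mi[0, 0], mi[0, 1], mi[1, 0], mi[1, 1], *ti])
        raise ValueError("polynomial2 has no closed-form inverse")


def identity_transform(model: str = "similarity") -> Transformation:
    if model == "similarity":
        return Transformation("similarity", [1.0, 0.0, 0.0, 0.0])
    if model == "affine":
        return Transformation("affine", [1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    return Transformation(
        "polynomial2", [0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0]
    )


def similarity_from_pose(
    rotation_deg: float, scale: float, tx: float, ty: float,
    center: tuple[float, float] = (0.0, 0.0),
) -> Transformation:
    """Similarity rotating by *rotation_deg* and scaling about *center*, then
    translating by (tx, ty)."""
    th = math.radians(rotation_deg)
    a = scale * math.cos(th)
    b = scale * math.sin(th)
    cx, cy = center
    tx2 = cx - (a * cx - b * cy) + tx
    ty2 = cy - (b * cx + a * cy) + ty
    return Transformation("similarity", [a, b, tx2, ty2])


def fit_transform(src: np.ndarray, dst: np.ndarray, model: str) -> Transformation:
    """Least-squares fit of *model* mapping src (moving) to dst (fixed).

    Raises ``ValueError`` for too few pairs or degenerate geometry
    (coincident points for similarity, collinear for affine, rank-deficient
    quadratic basis for polynomial2).
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (K, 2) arrays")
    k = len(src)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if k < _MIN_PAIRS[model]:
        raise ValueError(f"{model} needs >= {_MIN_PAIRS[model]} pairs, got {k}")
    x, y = src[:, 0], src[:, 1]
    if model == "similarity":
        zeros, ones = np.zeros(k), np.ones(k)
        a_mat = np.block(
            [[x[:, None], -y[:, None], ones[:, None], zeros[:, None]],
             [y[:, None], x[:, None], zeros[:, None], ones[:, None]]]
        )
        rhs = np.concatenate([dst[:, 0], dst[:, 1]])
        sol, _, rank, _ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        if rank < 4:
            raise ValueError("degenerate similarity fit: coincident points")
        return Transformation("similarity", sol)
    if model == "affine":
        basis = np.column_stack([x, y, np.ones(k)])
        if np.linalg.matrix_rank(basis) < 3:
            raise ValueError("degenerate affine fit: collinear points")
        sol, *_ = np.linalg.lstsq(basis, dst, rcond=None)
        # sol rows: coefficients of [x, y, 1] per output column
        return Transformation(
            "affine", [sol[0, 0], sol[1, 0], sol[0, 1], sol[1, 1], sol[2, 0], sol[2, 1]]
        )
    basis = _poly2_basis(src)
    if np.linalg.matrix_rank(basis) < 6:
        raise ValueError("degenerate polynomial2 fit: rank-deficient quadratic basis")
    sol, *_ = np.linalg.lstsq(basis, dst, rcond=None)
    return Transformation("polynomial2", np.concatenate([sol[:, 0], sol[:, 1]]))


@dataclass(frozen=True)
class MsacConfig:
    max_trials: int = 8000
    max_distances: tuple = (1.0, 20.0, 60.0, 80.0)
    repeats_per_distance: int = 1000
    seed: int = 0
    confidence: float = 0.99  # adaptive early-exit level

    def __post_init__(self):
        if self.max_trials <= 0 or self.repeats_per_distance <= 0:
            raise ValueError("max_trials and repeats_per_distance must be positive")
        if list(self.max_distances) != sorted(self.max_distances) or min(self.max_distances) <= 0:
            raise ValueError("max_distances must be positive and ascending")


def msac(
    pts_fixed: np.ndarray,
    pts_moving: np.ndarray,
    max_distance: float,
    trials: int = 8000,
    rng: np.random.Generator | int | None = None,
    confidence: float = 0.99,
) -> np.ndarray:
    """MSAC outlier rejection over matched point arrays.

    Hypotheses are similarity transforms from 2-point minimal samples (the
    cheapest geometric hypothesis; the final model is refit afterwards).
    Returns the indices of the best hypothesis' inliers (residual <=
    max_distance).  Adaptive early exit at *confidence* is a documented
    optimization; results remain deterministic for a fixed rng state.
    """
    pts_fixed = np.atleast_2d(pts_fixed).astype(np.float64)
    pts_moving = np.atleast_2d(pts_moving).astype(np.float64)
    n = len(pts_fixed)
    if n < 2:
        return np.empty(0, dtype=np.intp)
    rng = np.random.default_rng(rng)
    zm = pts_moving[:, 0] + 1j * pts_moving[:, 1]
    zf = pts_fixed[:, 0] + 1j * pts_fixed[:, 1]
    d2max = max_distance**2

    best_cost = np.inf
    best_inliers = np.empty(0, dtype=np.intp)
    done = 0
    needed = trials
    chunk = 256
    while done < min(trials, needed):
        t = min(chunk, trials - done)
        i1 = rng.integers(0, n, size=t)
        i2 = rng.integers(0, n, size=t)
        # similarity from two pairs in complex form: zf = A zm + B
        dz = zm[i2] - zm[i1]
        valid = (i1 != i2) & (np.abs(dz) > 1e-12)
        a_coef = np.where(valid, (zf[i2] - zf[i1]) / np.where(valid, dz, 1.0), 0.0)
        b_coef = zf[i1] - a_coef * zm[i1]
        resid2 = np.abs(a_coef[:, None] * zm[None, :] + b_coef[:, None] - zf[None, :]) ** 2
        costs = np.minimum(resid2, d2max).sum(axis=1)
        costs[~valid] = np.inf
        j = int(np.argmin(costs))
        if costs[j] < best_cost:
            best_cost = costs[j]
            best_inliers = np.nonzero(resid2[j] <= d2max)[0]
            w = max(len(best_inliers) / n, 1e-9)
            if w >= 1.0:
                needed = done + t
            else:
                needed = math.ceil(math.log(1 - confidence) / math.log(1 - w * w))
        done += t
    return best_inliers.astype(np.intp)


def select_model(n_inliers: int) -> str:
    """Transformation model by inlier count: <=8 similarity, 9..30 affine,
    >30 second-order polynomial."""
    if n_inliers < 0:
        raise ValueError("inlier count must be non-negative")
    if n_inliers <= 8:
        return "similarity"
    if n_inliers <= 30:
        return "affine"
    return "polynomial2"


@dataclass(frozen=True)
class RegistrationConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    hog_window: int = 32
    ratio_threshold: float = DEFAULT_RATIO
    msac: MsacConfig = field(default_factory=MsacConfig)


@dataclass
class RegistrationResult:
    status: str                      # "success" | "failed"
    transformation: Transformation | None = None
    inlier_indices: np.ndarray | None = None
    n_inliers: int = 0
    tre: float | None = None
    selected_distance: float | None = None
    model: str | None = None
    n_features_fixed: int = 0
    n_features_moving: int = 0
    n_matches: int = 0
    reason: str | None = None


def _round_seed(seed: int, d_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, d_index, rep]))


def register_matches(
    pts_fixed: np.ndarray,
    pts_moving: np.ndarray,
    cfg: MsacConfig = MsacConfig(),
    landmarks: LandmarkSet | None = None,
) -> RegistrationResult:
    """Repeated MSAC + model fit over matched point arrays; best round wins.

    With *landmarks*, the round with the smallest TRE is selected (the
    ground-truth evaluation protocol); without, the round with most inliers,
    ties broken by smallest mean inlier residual.
    """
    n = len(pts_fixed)
    result = RegistrationResult(status="failed", n_matches=n)
    if n < 2:
        result.reason = "fewer than 2 matches"
        return result

    best_key = None
    for di, dist in enumerate(cfg.max_distances):
        for rep in range(cfg.repeats_per_distance):
            rng = _round_seed(cfg.seed, di, rep)
            inl = msac(pts_fixed, pts_moving, dist, cfg.max_trials, rng, cfg.confidence)
            if len(inl) < 2:
                continue
            model = select_model(len(inl))
            try:
                t = fit_transform(pts_moving[inl], pts_fixed[inl], model)
            except ValueError:
                continue
            resid = np.linalg.norm(t.apply(pts_moving[inl]) - pts_fixed[inl], axis=1)
            if landmarks is not None:
                round_tre = tre(landmarks, t)
                key = (round_tre,)
            else:
                round_tre = None
                key = (-len(inl), float(resid.mean()))
            if best_key is None or key < best_key:
                best_key = key
                result = RegistrationResult(
                    status="success",
                    transformation=t,
                    inlier_indices=inl,
                    n_inliers=len(inl),
                    tre=round_tre,
                    selected_distance=float(dist),
                    model=model,
                    n_matches=n,
                )
    if result.status == "failed":
        result.reason = "no MSAC round produced a valid fit"
    return result


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    cfg: RegistrationConfig = RegistrationConfig(),
    landmarks: LandmarkSet | None = None,
) -> RegistrationResult:
    """Full pipeline: detect, describe, match once, then repeated MSAC + fit."""
    fixed = validate_gray(fixed)
    moving = validate_gray(moving)
    feats_f = detect(fixed, cfg.detector)
    feats_m = detect(moving, cfg.detector)
    if not feats_f or not feats_m:
        return RegistrationResult(
            status="failed",
            n_features_fixed=len(feats_f),
            n_features_moving=len(feats_m),
            reason="no features detected",
        )
    desc_f = extract_all(fixed, feats_f, window=cfg.hog_window)
    desc_m = extract_all(moving, feats_m, window=cfg.hog_window)
    matches = match_descriptors(desc_f, desc_m, cfg.ratio_threshold)
    arr_f = features_to_array(feats_f)[:, :2]
    arr_m = features_to_array(feats_m)[:, :2]
    if not matches:
        return RegistrationResult(
            status="failed",
            n_features_fixed=len(feats_f),
            n_features_moving=len(feats_m),
            n_matches=0,
            reason="no matches",
        )
    pts_f = arr_f[[m.idx_fixed for m in matches]]
    pts_m = arr_m[[m.idx_moving for m in matches]]
    result = register_matches(pts_f, pts_m, cfg.msac, landmarks)
    result.n_features_fixed = len(feats_f)
    result.n_features_moving = len(feats_m)
    return result


def warp_image(
    moving: np.ndarray,
    t: Transformation,
    out_shape: tuple[int, int],
    return_mask: bool = False,
):
    """Resample *moving* into the fixed frame under the moving->fixed map *t*.

    Inverse-mapped bilinear resampling: each fixed-frame pixel is pulled from
    t^{-1}(x, y) in the moving image; out-of-domain pixels are 0 and flagged
    in the mask.  For polynomial2 (no closed-form inverse) the inverse map is
    itself fit as a second-order polynomial on a dense grid of forward-mapped
    sample points.
    """
    moving = np.asarray(moving, dtype=np.float64)
    if t.model in ("similarity", "affine"):
        t_inv = t.inverse()
    else:
        gy, gx = np.mgrid[0 : moving.shape[0] : 24j, 0 : moving.shape[1] : 24j]
        src = np.column_stack([gx.ravel(), gy.ravel()])
        fwd = t.apply(src)
        t_inv = fit_transform(fwd, src, "polynomial2")
    n, m = out_shape
    yy, xx = np.mgrid[0:n, 0:m]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    src = t_inv.apply(pts)
    sx = src[:, 0].reshape(n, m)
    sy = src[:, 1].reshape(n, m)
    inside = (sx >= 0) & (sx <= moving.shape[1] - 1) & (sy >= 0) & (sy <= moving.shape[0] - 1)
    warped = ndimage.map_coordinates(moving, [sy, sx], order=1, mode="constant", cval=0.0)
    warped[~inside] = 0.0
    if return_mask:
        return warped, inside
    return warped
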