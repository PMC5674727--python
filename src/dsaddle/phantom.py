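"""Synthetic fundus phantoms with known ground-truth transformations.

The generator emulates the gross appearance of a fundus photograph: a
circular field of view (FOV) on a dark frame, a branching vessel tree whose
widths and contrasts span configurable ranges, a bright optic disc,
multiplicative illumination falloff toward the frame boundary, dark-spot
occlusions, and additive Gaussian noise.  Vessels have Gaussian-valley
cross-sections, so band-pass filtering produces the saddle structure the
detector targets, and the generator returns the vessel centerline mask as an
oracle for detector tests.

Image pairs are cut from one extended scene (so anatomy exists beyond the
fixed FOV) related by a known similarity, affine, or second-order polynomial
transform, with the translation solved to hit a requested FOV overlap.  The
two frames are degraded independently (fresh noise, shifted illumination,
fresh dark spots).  Category S pairs have large overlap (super-resolution),
category P small overlap (mosaicking), and category A additionally perturbs
the anatomy of the moving frame (vessel jitter plus small lesions),
mimicking longitudinal change.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .evaluation import LandmarkSet
from .image import load_image, save_image
from .registration import Transformation, fit_transform, similarity_from_pose

logger = logging.getLogger(__name__)

FOV_RADIUS_FRAC = 0.48
BACKGROUND = 0.03
BASE_INTENSITY = 0.55
DISC_BRIGHTNESS = 0.25

#: per-category (overlap range, rotation range in degrees), matching the
#: regimes of the three registration applications
CATEGORY_RANGES = {
    "S": ((0.86, 1.00), (0.0, 5.0)),
    "P": ((0.17, 0.89), (0.0, 7.0)),
    "A": ((0.95, 1.00), (0.0, 4.0)),
}


@dataclass(frozen=True)
class PhantomConfig:
    size: int = 583
    n_vessels: int = 7
    vessel_width_range: tuple = (2.0, 12.0)
    vessel_contrast_range: tuple = (0.05, 0.5)
    illumination_gradient: float = 0.35
    n_dark_spots: int = 2
    dark_spot_radius_range: tuple = (10.0, 40.0)
    dark_spot_depth_range: tuple = (0.2, 0.5)
    # sensor noise std at NATIVE resolution; the working frame is an
    # anti-aliased downsample (factor below), which attenuates and spatially
    # correlates the noise exactly as the acquisition chain does
    noise_sigma: float = 0.02
    downsample_factor: float = 5.0
    # band-limited choroidal/pigmentation texture of the fundus background:
    # smooth intensity mottle (std, correlation length in px)
    texture_amp: float = 0.02
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("phantom size must be >= 64")
        for lo, hi in (self.vessel_width_range, self.vessel_contrast_range,
                       self.dark_spot_radius_range, self.dark_spot_depth_range):
            if not (0 <= lo <= hi):
                raise ValueError("ranges must be non-negative and ordered")
        if self.n_vessels < 0 or self.n_dark_spots < 0 or self.noise_sigma < 0:
            raise ValueError("counts and noise_sigma must be non-negative")


@dataclass(frozen=True)
class TransformSpec:
    """Ground-truth warp request; None fields are sampled per category."""

    model: str = "similarity"
    rotation_deg: float | None = None
    scale: float | None = None
    overlap: float | None = None
    shear: float = 0.02        # affine shear half-range
    quad_amp: float = 2.0      # polynomial2 edge displacement, px


@dataclass
class PhantomPair:
    fixed: np.ndarray
    moving: np.ndarray
    true_transform: Transformation
    landmarks: LandmarkSet  # working-resolution coordinates
    overlap_fraction: float
    category: str
    seed: int


# ---------------------------------------------------------------------------
# scene construction


@dataclass
class _Segment:
    points: np.ndarray  # (K, 2) of (y, x), float
    width: float
    contrast: float


def _grow_tree(rng: np.random.Generator, canvas: int, cfg: PhantomConfig,
               disc_yx: tuple[float, float]) -> list[_Segment]:
    w_lo, w_hi = cfg.vessel_width_range
    c_lo, c_hi = cfg.vessel_contrast_range
    segments: list[_Segment] = []
    max_steps = int(canvas * 0.9)

    def walk(y, x, angle, width, contrast, depth):
        pts = [(y, x)]
        for step in range(max_steps):
            angle += rng.normal(0.0, 0.07)
            y += 2.0 * math.sin(angle)
            x += 2.0 * math.cos(angle)
            if not (2 <= y < canvas - 2 and 2 <= x < canvas - 2):
                break
            pts.append((y, x))
            if depth < 2 and step > 20 and rng.random() < 0.012:
                child_w = max(w_lo, width * rng.uniform(0.55, 0.8))
                child_c = max(c_lo, contrast * rng.uniform(0.7, 0.95))
                walk(y, x, angle + rng.choice([-1, 1]) * rng.uniform(0.35, 0.8),
                     child_w, child_c, depth + 1)
        if len(pts) > 4:
            segments.append(_Segment(np.array(pts), width, contrast))

    dy, dx = disc_yx
    for i in range(cfg.n_vessels):
        angle = 2 * math.pi * (i + rng.uniform(-0.2, 0.2)) / max(cfg.n_vessels, 1)
        y0 = dy + 6.0 * math.sin(angle)
        x0 = dx + 6.0 * math.cos(angle)
        # main trunks biased toward the wide end of the calibre range
        width = w_lo + (w_hi - w_lo) * rng.uniform(0.4, 1.0)
        contrast = rng.uniform(c_lo, c_hi)
        walk(y0, x0, angle, width, contrast, 0)
    return segments


def _stamp_valleys(shape: tuple[int, int], segments: list[_Segment]):
    """Max-combined Gaussian-valley depth map plus the centerline mask."""
    valley = np.zeros(shape)
    centerline = np.zeros(shape, dtype=bool)
    for seg in segments:
        sigma = max(seg.width / 2.0, 0.6)
        pad = int(math.ceil(3 * sigma)) + 2
        iy = np.clip(np.round(seg.points[:, 0]).astype(int), 0, shape[0] - 1)
        ix = np.clip(np.round(seg.points[:, 1]).astype(int), 0, shape[1] - 1)
        y0, y1 = max(iy.min() - pad, 0), min(iy.max() + pad + 1, shape[0])
        x0, x1 = max(ix.min() - pad, 0), min(ix.max() + pad + 1, shape[1])
        local = np.zeros((y1 - y0, x1 - x0), dtype=bool)
        local[iy - y0, ix - x0] = True
        dist = ndimage.distance_transform_edt(~local)
        depth = seg.contrast * np.exp(-(dist**2) / (2 * sigma**2))
        np.maximum(valley[y0:y1, x0:x1], depth, out=valley[y0:y1, x0:x1])
        centerline[iy, ix] = True
    return valley, centerline


def _build_scene(cfg: PhantomConfig, rng: np.random.Generator, canvas: int):
    """Noise-free scene (base + disc - vessel valleys) on a canvas, plus the
    centerline mask and the reusable segment list."""
    cy = cx = canvas / 2.0
    disc_yx = (cy + rng.uniform(-0.05, 0.05) * canvas,
               cx - 0.20 * cfg.size + rng.uniform(-0.03, 0.03) * canvas)
    segments = _grow_tree(rng, canvas, cfg, disc_yx)
    valley, centerline = _stamp_valleys((canvas, canvas), segments)
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    d2_disc = (yy - disc_yx[0]) ** 2 + (xx - disc_yx[1]) ** 2
    disc_sigma = 0.045 * cfg.size
    scene = BASE_INTENSITY + DISC_BRIGHTNESS * np.exp(-d2_disc / (2 * disc_sigma**2))
    if cfg.texture_amp > 0:
        mottle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (canvas, canvas)),
                                         cfg.texture_scale)
        scene = scene + cfg.texture_amp * mottle / max(mottle.std(), 1e-12)
    scene = scene - valley
    return np.clip(scene, 0.0, 1.0), centerline, segments


def _fov_mask(size: int, radius_frac: float = FOV_RADIUS_FRAC) -> np.ndarray:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius_frac * size) ** 2


def _degrade(frame: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame degradations: illumination falloff, dark spots, noise, FOV."""
    size = frame.shape[0]
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) / (FOV_RADIUS_FRAC * size)
    g = cfg.illumination_gradient
    illum = 1.0 - g * np.clip(r, 0, 1.2) ** 4
    phi = rng.uniform(0, 2 * math.pi)
    lateral = 1.0 - 0.3 * g * (
        ((xx - c) * math.cos(phi) + (yy - c) * math.sin(phi)) / size + 0.5
    ) * 0.5
    out = frame * illum * lateral
    r_lo, r_hi = cfg.dark_spot_radius_range
    d_lo, d_hi = cfg.dark_spot_depth_range
    for _ in range(cfg.n_dark_spots):
        sy = rng.uniform(0.15 * size, 0.85 * size)
        sx = rng.uniform(0.15 * size, 0.85 * size)
        rad = rng.uniform(r_lo, r_hi)
        depth = rng.uniform(d_lo, d_hi)
        d2 = (yy - sy) ** 2 + (xx - sx) ** 2
        out = out * (1.0 - depth * np.exp(-d2 / (2 * rad**2)))
    fov = _fov_mask(size)
    out = np.where(fov, out, BACKGROUND)
    if cfg.noise_sigma > 0:
        # white sensor noise seen through the anti-aliased f:1 downsample:
        # the Gaussian AA kernel (sigma_aa = (f-1)/2 native px) attenuates the
        # std by 2*sigma_aa*sqrt(pi) and leaves a sigma_aa/f px correlation
        f = cfg.downsample_factor
        white = rng.normal(0.0, 1.0, out.shape)
        if f > 1:
            sigma_aa = (f - 1.0) / 2.0
            working_std = cfg.noise_sigma / (2.0 * sigma_aa * math.sqrt(math.pi))
            noise = ndimage.gaussian_filter(white, sigma_aa / f)
            noise *= working_std / max(noise.std(), 1e-12)
        else:
            noise = cfg.noise_sigma * white
        out = out + noise
    return np.clip(out, 0.0, 1.0)


def generate_fundus(cfg: PhantomConfig = PhantomConfig()) -> tuple[np.ndarray, np.ndarray]:
    """One degraded fundus phantom plus its vessel centerline mask (oracle).

    Deterministic for a fixed config (all randomness flows from cfg.seed).
    """
    rng_scene = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    rng_deg = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    scene, centerline, _ = _build_scene(cfg, rng_scene, cfg.size)
    img = _degrade(scene, cfg, rng_deg)
    mask = centerline & _fov_mask(cfg.size)
    return img, mask


# ---------------------------------------------------------------------------
# pairs


def _overlap_to_distance(overlap: float, radius: float) -> float:
    """Center distance of two equal circles with the given intersection
    fraction (relative to one circle's area)."""
    if not (0.0 < overlap <= 1.0):
        raise ValueError(f"overlap must be in (0, 1], got {overlap}")
    if overlap >= 1.0:
        return 0.0

    def frac(d):
        u = d / (2 * radius)
        return (2 * math.acos(u) - math.sin(2 * math.acos(u))) / math.pi

    return brentq(lambda d: frac(d) - overlap, 0.0, 2.0 * radius - 1e-9)


def _make_true_transform(
    spec: TransformSpec, category: str, size: int, rng: np.random.Generator
) -> tuple[Transformation, float]:
    (ov_lo, ov_hi), (rot_lo, rot_hi) = CATEGORY_RANGES[category]
    overlap = spec.overlap if spec.overlap is not None else rng.uniform(ov_lo, ov_hi)
    rotation = (
        spec.rotation_deg if spec.rotation_deg is not None else rng.uniform(rot_lo, rot_hi)
    )
    scale = spec.scale if spec.scale is not None else 1.0 + rng.normal(0.0, 0.004)
    radius = FOV_RADIUS_FRAC * size
    d = _overlap_to_distance(overlap, radius)
    phi = rng.uniform(0, 2 * math.pi)
    tx, ty = d * math.cos(phi), d * math.sin(phi)
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    sim = similarity_from_pose(rotation, scale, tx, ty, center=center)
    if spec.model == "similarity":
        return sim, overlap
    if spec.model == "affine":
        # compose a small shear about the frame center with the similarity:
        # x_f = S(c + Sh(x_m - c)) where Sh = [[1, sh], [0, 1]]
        sh = rng.uniform(-spec.shear, spec.shear)
        a, b, tx0, ty0 = sim.params
        s_mat = np.array([[a, -b], [b, a]])
        m = s_mat @ np.array([[1.0, sh], [0.0, 1.0]])
        cvec = np.array(center)
        t0 = np.array([tx0, ty0]) + (s_mat - m) @ cvec
        aff = Transformation("affine", [m[0, 0], m[0, 1], m[1, 0], m[1, 1], t0[0], t0[1]])
        return aff, overlap
    if spec.model == "polynomial2":
        radius_n = radius
        coeffs = rng.uniform(-spec.quad_amp, spec.quad_amp, size=6)

        cx, cy = center

        def analytic(pts):
            pts = np.atleast_2d(pts)
            u = (pts[:, 0] - cx) / radius_n
            v = (pts[:, 1] - cy) / radius_n
            qx = coeffs[0] * u * u + coeffs[1] * u * v + coeffs[2] * v * v
            qy = coeffs[3] * u * u + coeffs[4] * u * v + coeffs[5] * v * v
            bent = pts + np.column_stack([qx, qy])
            return sim.apply(bent)

        # the composition is exactly quadratic in (x, y): recover its 12
        # coefficients from a grid fit (residual at machine precision)
        gy, gx = np.mgrid[0 : size : 7j, 0 : size : 7j]
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        t = fit_transform(grid, analytic(grid), "polynomial2")
        return t, overlap
    raise ValueError(f"unknown model {spec.model!r}")


def _invert_point(t: Transformation, target: np.ndarray, guess: np.ndarray) -> np.ndarray:
    """Solve t(x) = target by Newton iteration (needed for polynomial2)."""
    x = guess.astype(np.float64).copy()
    for _ in range(60):
        f = t.apply(x[None, :])[0] - target
        if np.abs(f).max() < 1e-10:
            break
        p = t.params
        if t.model == "polynomial2":
            cx_, cy_ = p[:6], p[6:]
            jac = np.array(
                [
                    [cx_[1] + 2 * cx_[3] * x[0] + cx_[4] * x[1],
                     cx_[2] + cx_[4] * x[0] + 2 * cx_[5] * x[1]],
                    [cy_[1] + 2 * cy_[3] * x[0] + cy_[4] * x[1],
                     cy_[2] + cy_[4] * x[0] + 2 * cy_[5] * x[1]],
                ]
            )
        elif t.model == "affine":
            jac = np.array([[p[0], p[1]], [p[2], p[3]]])
        else:
            jac = np.array([[p[0], -p[1]], [p[1], p[0]]])
        x = x - np.linalg.solve(jac, f)
    return x


def _inverse_map(t: Transformation, pts: np.ndarray) -> np.ndarray:
    if t.model in ("similarity", "affine"):
        return t.inverse().apply(pts)
    return np.array([_invert_point(t, p, p.copy()) for p in pts])


def _pick_landmarks(
    t: Transformation,
    centerline_fixed: np.ndarray,
    size: int,
    rng: np.random.Generator,
    n: int = 10,
) -> LandmarkSet:
    c = (size - 1) / 2.0
    radius = FOV_RADIUS_FRAC * size
    ys, xs = np.nonzero(centerline_fixed)
    pts_f = np.column_stack([xs, ys]).astype(np.float64)
    ok = np.linalg.norm(pts_f - [c, c], axis=1) <= 0.92 * radius
    pts_f = pts_f[ok]
    if len(pts_f) == 0:
        raise ValueError("no vessel centerline available for landmarks")
    pts_m = _inverse_map(t, pts_f)
    ok_m = np.linalg.norm(pts_m - [c, c], axis=1) <= 0.92 * radius
    pts_f, pts_m = pts_f[ok_m], pts_m[ok_m]
    if len(pts_f) == 0:
        raise ValueError("no centerline points visible in both fields of view")
    order = rng.permutation(len(pts_f))
    chosen: list[int] = []
    min_sep = size / 15.0
    while len(chosen) < n and min_sep >= 1.0:
        for i in order:
            if len(chosen) >= n:
                break
            if all(np.linalg.norm(pts_f[i] - pts_f[j]) >= min_sep for j in chosen):
                chosen.append(int(i))
        min_sep /= 2.0
    sel = np.array(chosen[:n])
    return LandmarkSet(pts_f[sel], pts_m[sel])


def _perturb_anatomy(segments: list[_Segment], canvas: int,
                     rng: np.random.Generator) -> list[_Segment]:
    """Longitudinal-change surrogate: smooth tortuosity jitter on a subset of
    vessels; small added lesions are handled separately as dark blobs."""
    out = []
    for seg in segments:
        pts = seg.points.copy()
        if rng.random() < 0.5 and len(pts) > 10:
            amp = rng.uniform(0.5, 2.0)
            noise = rng.normal(0.0, 1.0, size=(len(pts), 2))
            noise = ndimage.gaussian_filter1d(noise, sigma=8.0, axis=0)
            denom = max(np.abs(noise).max(), 1e-9)
            pts = pts + amp * noise / denom
            pts = np.clip(pts, 2, canvas - 3)
        out.append(_Segment(pts, seg.width, seg.contrast))
    return out


def generate_pair(
    cfg: PhantomConfig = PhantomConfig(),
    transform_spec: TransformSpec = TransformSpec(),
    category: str = "S",
) -> PhantomPair:
    """Fixed/moving phantom pair under a known ground-truth transform.

    The moving frame samples the extended scene through the inverse of the
    true (moving -> fixed) map and is degraded independently of the fixed
    frame.  Landmarks are 10 vessel-centerline points visible in both FOVs,
    consistent with the true transform to < 1e-6 px.
    """
    if category not in CATEGORY_RANGES:
        raise ValueError(f"unknown category {category!r}")
    size = cfg.size
    seed = cfg.seed
    rngs = {
        k: np.random.default_rng(np.random.SeedSequence([seed, i]))
        for i, k in enumerate(["scene", "geom", "deg_f", "deg_m", "anat", "lms"])
    }

    t, requested_overlap = _make_true_transform(transform_spec, category, size, rngs["geom"])

    # margin large enough that the moving FOV stays inside the canvas
    corners = np.array([[0, 0], [size - 1, 0], [0, size - 1], [size - 1, size - 1]], float)
    reach = np.abs(t.apply(corners) - corners).max()
    margin = int(math.ceil(reach)) + 16
    canvas = size + 2 * margin

    scene, centerline, segments = _build_scene(cfg, rngs["scene"], canvas)

    sl = slice(margin, margin + size)
    fixed = _degrade(scene[sl, sl], cfg, rngs["deg_f"])

    scene_m = scene
    if category == "A":
        seg_m = _perturb_anatomy(segments, canvas, rngs["anat"])
        valley_m, _ = _stamp_valleys((canvas, canvas), seg_m)
        scene_m = np.clip(scene + _stamp_valleys((canvas, canvas), segments)[0] - valley_m, 0, 1)
        for _ in range(rngs["anat"].integers(1, 4)):
            ly = rngs["anat"].uniform(margin, margin + size)
            lx = rngs["anat"].uniform(margin, margin + size)
            lr = rngs["anat"].uniform(3.0, 8.0)
            ld = rngs["anat"].uniform(0.1, 0.3)
            yy, xx = np.mgrid[0:canvas, 0:canvas]
            scene_m = np.clip(
                scene_m - ld * np.exp(-((yy - ly) ** 2 + (xx - lx) ** 2) / (2 * lr**2)),
                0, 1,
            )

    yy, xx = np.mgrid[0:size, 0:size]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    mapped = t.apply(pts) + margin  # moving-frame pixel -> scene coordinates
    moving_raw = ndimage.map_coordinates(
        scene_m, [mapped[:, 1].reshape(size, size), mapped[:, 0].reshape(size, size)],
        order=1, mode="constant", cval=BACKGROUND,
    )
    moving = _degrade(moving_raw, cfg, rngs["deg_m"])

    # measured overlap: moving-FOV pixels whose image lies in the fixed FOV
    fov = _fov_mask(size)
    c = (size - 1) / 2.0
    in_fixed = np.linalg.norm(t.apply(pts) - [c, c], axis=1).reshape(size, size) <= (
        FOV_RADIUS_FRAC * size
    )
    measured = float((fov & in_fixed).sum() / fov.sum())

    landmarks = _pick_landmarks(t, centerline[sl, sl], size, rngs["lms"])
    return PhantomPair(
        fixed=fixed,
        moving=moving,
        true_transform=t,
        landmarks=landmarks,
        overlap_fraction=measured,
        category=category,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixtures


def export_fixture(pair: PhantomPair, directory) -> dict:
    """Write fixed.png, moving.png, landmarks.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_image(directory / "fixed.png", pair.fixed)
    save_image(directory / "moving.png", pair.moving)
    pair.landmarks.to_csv(directory / "landmarks.csv")
    truth = {
        "model": pair.true_transform.model,
        "params": pair.true_transform.params.tolist(),
        "overlap_fraction": pair.overlap_fraction,
        "category": pair.category,
        "seed": pair.seed,
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


def load_fixture(directory):
    """Read back a fixture directory: (fixed, moving, landmarks, truth)."""
    directory = Path(directory)
    fixed = load_image(directory / "fixed.png")
    moving = load_image(directory / "moving.png")
    landmarks = LandmarkSet.from_csv(directory / "landmarks.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    truth["transform"] = Transformation(truth["model"], np.array(truth["params"]))
    return fixed, moving, landmarks, truth
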