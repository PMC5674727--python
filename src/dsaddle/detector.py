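"""Saddle-point feature detection on the DoG pyramid.

A saddle point is a pixel whose surround shows two darker and two brighter
sectors alternating on a ring — the signature of a concave/convex 3D
intensity profile, which vessel crossings and vessel-background transitions
produce in band-pass filtered fundus images.  Detection runs per octave of
the normalized absolute DoG pyramid:

1. enumerate candidate pixels far enough from the border for a radius-3 ring;
2. inner-ring test: of the 8-neighborhood, two opposite pixels (axial "+" or
   diagonal "x" arrangement) must both be strictly brighter than both pixels
   of the orthogonal pair, in either polarity; the central level beta is the
   median of the passing shape's 4 pixels (8 if both shapes pass);
3. outer-ring test: the 16 pixels of the radius-3 digital circle are labeled
   darker (d) / similar (s) / lighter (l) relative to beta with tolerance
   epsilon, and must form alternating d/l arcs of length 2..8, with neutral
   s-runs no longer than 2 between them;
4. non-maxima suppression (3x3, octave 0 only) on a contrast-based response;
5. subpixel refinement by a quadratic fit to the 3x3 DoG neighborhood;
6. lifting of octave coordinates back to the input image frame.

The inner test alone typically rejects on the order of 80% of candidates,
which is what keeps the detector fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import validate_gray
from .pyramid import (
    DEFAULT_K,
    DEFAULT_N_OCTAVES,
    DEFAULT_SIGMA0,
    DoGOctave,
    build_pyramid,
)

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.0010

# Inner ring: the 8-neighborhood, clockwise from 12 o'clock, as (dy, dx).
INNER_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
# indices into the inner ring
_TOP, _NE, _RIGHT, _SE, _BOTTOM, _SW, _LEFT, _NW = range(8)

# Outer ring: the 16-pixel radius-3 digital (Bresenham) circle, clockwise
# from 12 o'clock, as (dy, dx).  4 axial extremes at distance 3, 12 between.
OUTER_OFFSETS = np.array(
    [
        (-3, 0), (-3, 1), (-2, 2), (-1, 3),
        (0, 3), (1, 3), (2, 2), (3, 1),
        (3, 0), (3, -1), (2, -2), (1, -3),
        (0, -3), (-1, -3), (-2, -2), (-3, -1),
    ]
)

# integer codes for the three outer-ring labels
LABEL_D, LABEL_S, LABEL_L = 0, 1, 2
_LABEL_CHARS = np.array(["d", "s", "l"])


@dataclass(frozen=True)
class DetectorConfig:
    sigma0: float = DEFAULT_SIGMA0
    k: float = DEFAULT_K
    n_octaves: int = DEFAULT_N_OCTAVES
    epsilon: float = DEFAULT_EPSILON


@dataclass(frozen=True)
class FeaturePoint:
    """A detected saddle point in input-image coordinates (0-based, subpixel)."""

    x: float
    y: float
    octave: int
    response: float
    beta: float


@dataclass
class DetectionStats:
    """Per-octave candidate bookkeeping (used to audit test selectivity)."""

    n_candidates: list[int] = field(default_factory=list)
    n_inner_pass: list[int] = field(default_factory=list)
    n_outer_pass: list[int] = field(default_factory=list)

    @property
    def inner_rejection_fraction(self) -> float:
        """Fraction of all candidates (all octaves) failing the inner test."""
        total = sum(self.n_candidates)
        if total == 0:
            return float("nan")
        return 1.0 - sum(self.n_inner_pass) / total


def candidate_grid(octave: DoGOctave) -> np.ndarray:
    """Integer candidate lattice for an octave, as an (K, 2) array of (y, x).

    0-based bounds are [3, N-4] x [3, M-4] inclusive (the radius-3 ring must
    fit); images narrower than 7 pixels yield no candidates.
    """
    n, m = octave.shape
    if m < 7 or n < 7:
        logger.info("octave %d (%dx%d) too small for candidates", octave.octave_index, m, n)
        return np.empty((0, 2), dtype=np.intp)
    ys, xs = np.mgrid[3 : n - 3, 3 : m - 3]
    return np.column_stack([ys.ravel(), xs.ravel()])


def sample_rings(octave: DoGOctave, y: int, x: int) -> tuple[np.ndarray, np.ndarray]:
    """Inner (8) and outer (16) ring intensities around candidate (y, x)."""
    n, m = octave.shape
    if not (3 <= y <= n - 4 and 3 <= x <= m - 4):
        raise ValueError(f"candidate ({y}, {x}) violates ring bounds for {n}x{m} octave")
    d = octave.dog
    inner = d[y + INNER_OFFSETS[:, 0], x + INNER_OFFSETS[:, 1]]
    outer = d[y + OUTER_OFFSETS[:, 0], x + OUTER_OFFSETS[:, 1]]
    return inner, outer


@dataclass(frozen=True)
class InnerTestResult:
    passed: bool
    shapes: frozenset
    beta: float | None


def inner_ring_test(inner: np.ndarray) -> InnerTestResult:
    """Apply the +/x pattern test to an 8-vector of inner-ring intensities.

    A shape passes when the minimum of one opposite pair strictly exceeds the
    maximum of the orthogonal pair (either polarity).  beta is the median of
    the 4 pixels of the passing shape, or of all 8 when both shapes pass.
    """
    inner = np.asarray(inner, dtype=np.float64)
    t, b = inner[_TOP], inner[_BOTTOM]
    l, r = inner[_LEFT], inner[_RIGHT]
    ne, sw = inner[_NE], inner[_SW]
    nw, se = inner[_NW], inner[_SE]

    plus = min(t, b) > max(l, r) or min(l, r) > max(t, b)
    cross = min(ne, sw) > max(nw, se) or min(nw, se) > max(ne, sw)

    if not (plus or cross):
        return InnerTestResult(False, frozenset(), None)
    shapes = set()
    if plus:
        shapes.add("+")
    if cross:
        shapes.add("x")
    if plus and cross:
        beta = float(np.median(inner))
    elif plus:
        beta = float(np.median([t, b, l, r]))
    else:
        beta = float(np.median([ne, sw, nw, se]))
    return InnerTestResult(True, frozenset(shapes), beta)


def label_outer(outer: np.ndarray, beta: float, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Three-way label of the outer ring relative to beta.

    d: I < beta - epsilon;  s: beta - epsilon <= I <= beta + epsilon
    (boundaries inclusive);  l: I > beta + epsilon.  Returns int codes
    (LABEL_D/S/L).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    outer = np.asarray(outer, dtype=np.float64)
    labels = np.full(outer.shape, LABEL_S, dtype=np.int8)
    labels[outer < beta - epsilon] = LABEL_D
    labels[outer > beta + epsilon] = LABEL_L
    return labels


def labels_to_str(labels: np.ndarray) -> str:
    return "".join(_LABEL_CHARS[labels])


def _cyclic_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal cyclic runs of a label sequence as (label, length) pairs."""
    n = len(labels)
    if np.all(labels == labels[0]):
        return [(int(labels[0]), n)]
    # rotate so index 0 starts a run
    start = 0
    while labels[start - 1] == labels[start]:
        start -= 1
    rot = np.roll(labels, -start % n) if start % n else labels
    runs: list[tuple[int, int]] = []
    for lab in rot:
        if runs and runs[-1][0] == lab:
            runs[-1] = (runs[-1][0], runs[-1][1] + 1)
        else:
            runs.append((int(lab), 1))
    return runs


def outer_ring_test(labels: np.ndarray) -> bool:
    """Saddle arc test on a 16-long cyclic label sequence.

    Pass iff every neutral s-run is at most 2 long; after removing s-runs the
    remaining d/l arcs strictly alternate cyclically, each arc is 2..8 long,
    and there are at least two arcs of each polarity.
    """
    labels = np.asarray(labels)
    runs = _cyclic_runs(labels)
    if any(lab == LABEL_S and length > 2 for lab, length in runs):
        return False
    arcs = [(lab, length) for lab, length in runs if lab != LABEL_S]
    if len(arcs) < 4:  # need >= 2 dark and >= 2 light sectors
        return False
    for i, (lab, length) in enumerate(arcs):
        if not (2 <= length <= 8):
            return False
        if lab == arcs[(i + 1) % len(arcs)][0]:
            return False
    n_d = sum(1 for lab, _ in arcs if lab == LABEL_D)
    n_l = len(arcs) - n_d
    return n_d >= 2 and n_l >= 2


def response_strength(outer: np.ndarray, labels: np.ndarray, beta: float) -> float:
    """Contrast of the saddle pattern about beta.

    Mean deficit of the d-pixels plus mean excess of the l-pixels; zero when
    either polarity is absent.  Monotone in contrast, which is all the
    non-maxima suppression needs.
    """
    outer = np.asarray(outer, dtype=np.float64)
    d_mask = labels == LABEL_D
    l_mask = labels == LABEL_L
    if not d_mask.any() or not l_mask.any():
        return 0.0
    return float((beta - outer[d_mask]).mean() + (outer[l_mask] - beta).mean())


def nonmax_suppress(
    points: list[tuple[int, int, float]], octave_index: int
) -> list[tuple[int, int, float]]:
    """3x3 non-maxima suppression over passing points of one octave.

    Applied only to octave 0 (higher octaves are already coarse); a point
    survives iff its response is >= every passing neighbor's, with ties kept
    by the lexicographically smallest (y, x).  *points* are (y, x, response).
    """
    if octave_index != 0:
        return list(points)
    by_pos = {(y, x): r for y, x, r in points}
    kept = []
    for y, x, r in points:
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                rq = by_pos.get((y + dy, x + dx))
                if rq is None:
                    continue
                if rq > r or (rq == r and (y + dy, x + dx) < (y, x)):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            kept.append((y, x, r))
    return kept


# least-squares fit of f = c0 + c1*x + c2*y + c3*x^2 + c4*xy + c5*y^2
# on the 3x3 grid; pseudo-inverse precomputed once.
_QX, _QY = np.meshgrid([-1, 0, 1], [-1, 0, 1])
_QA = np.column_stack(
    [
        np.ones(9),
        _QX.ravel(),
        _QY.ravel(),
        _QX.ravel() ** 2,
        (_QX * _QY).ravel(),
        _QY.ravel() ** 2,
    ]
)
_QPINV = np.linalg.pinv(_QA)


def subpixel_refine(octave: DoGOctave, y: int, x: int) -> tuple[float, float]:
    """Subpixel peak position from a quadratic fit to the 3x3 |DoG| patch.

    Returns (x + dx, y + dy) in octave coordinates with each offset clamped
    to [-0.5, 0.5]; a degenerate (singular) fit leaves the integer position.
    """
    patch = octave.dog[y - 1 : y + 2, x - 1 : x + 2].ravel()
    c = _QPINV @ patch
    dx, dy = _solve_quadratic_offset(c)
    return (x + dx, y + dy)


def _solve_quadratic_offset(c: np.ndarray) -> tuple[float, float]:
    # stationary point of the fitted quadratic: H [dx dy]' = -g
    h = np.array([[2 * c[3], c[4]], [c[4], 2 * c[5]]])
    g = np.array([c[1], c[2]])
    det = h[0, 0] * h[1, 1] - h[0, 1] * h[1, 0]
    if abs(det) < 1e-12:
        # ridge-degenerate surface: refine each axis by its 1D parabola
        dx = -c[1] / (2 * c[3]) if abs(c[3]) > 1e-12 else 0.0
        dy = -c[2] / (2 * c[5]) if abs(c[5]) > 1e-12 else 0.0
    else:
        dx, dy = -np.linalg.solve(h, g)
    return float(np.clip(dx, -0.5, 0.5)), float(np.clip(dy, -0.5, 0.5))


def to_input_coords(x: float, y: float, octave_index: int) -> tuple[float, float]:
    """Lift octave coordinates to the input-image frame (factor 2^octave).

    Evaluation at a different native resolution further rescales by
    (original_dim / working_dim); that step belongs to the evaluation stage.
    """
    f = 2 ** octave_index
    return (x * f, y * f)


# ---------------------------------------------------------------------------
# vectorized per-octave detection


def _inner_test_grid(d: np.ndarray):
    """Vectorized inner-ring test over the whole candidate lattice of a DoG
    image.  Returns (ys, xs, pass_mask, beta, n_candidates)."""
    n, m = d.shape
    if n < 7 or m < 7:
        return None
    c = d[3 : n - 3, 3 : m - 3]  # centers (unused value, defines the lattice)
    shifted = {
        (dy, dx): d[3 + dy : n - 3 + dy, 3 + dx : m - 3 + dx]
        for dy, dx in map(tuple, INNER_OFFSETS)
    }
    t, b = shifted[(-1, 0)], shifted[(1, 0)]
    l, r = shifted[(0, -1)], shifted[(0, 1)]
    ne, sw = shifted[(-1, 1)], shifted[(1, -1)]
    nw, se = shifted[(-1, -1)], shifted[(1, 1)]

    plus = (np.minimum(t, b) > np.maximum(l, r)) | (np.minimum(l, r) > np.maximum(t, b))
    cross = (np.minimum(ne, sw) > np.maximum(nw, se)) | (
        np.minimum(nw, se) > np.maximum(ne, sw)
    )
    passed = plus | cross

    # median of the passing shape's pixels (4), or all 8 when both pass
    axial = np.stack([t, b, l, r])
    diag = np.stack([ne, sw, nw, se])
    med_axial = np.median(axial, axis=0)
    med_diag = np.median(diag, axis=0)
    med_all = np.median(np.concatenate([axial, diag]), axis=0)
    beta = np.where(plus & cross, med_all, np.where(plus, med_axial, med_diag))

    ys, xs = np.nonzero(passed)
    return ys + 3, xs + 3, beta[passed], c.size


def detect(
    img: np.ndarray,
    cfg: DetectorConfig = DetectorConfig(),
    return_stats: bool = False,
):
    """Run the full detector on a [0, 1] gray image.

    Deterministic for fixed input and config.  Returns the feature points in
    input-image coordinates, sorted by (octave, y, x); with
    ``return_stats=True`` also returns per-octave candidate statistics.
    """
    img = validate_gray(img)
    pyr = build_pyramid(img, cfg.sigma0, cfg.k, cfg.n_octaves)
    stats = DetectionStats()
    features: list[FeaturePoint] = []

    for octave in pyr.octaves:
        d = octave.dog
        grid = _inner_test_grid(d)
        if grid is None:
            stats.n_candidates.append(0)
            stats.n_inner_pass.append(0)
            stats.n_outer_pass.append(0)
            continue
        ys, xs, betas, n_cand = grid
        stats.n_candidates.append(n_cand)
        stats.n_inner_pass.append(len(ys))

        if len(ys) == 0:
            stats.n_outer_pass.append(0)
            continue

        # gather outer rings for inner-pass candidates: (K, 16)
        outer = np.stack(
            [d[ys + dy, xs + dx] for dy, dx in map(tuple, OUTER_OFFSETS)], axis=1
        )
        eps = cfg.epsilon
        labels = np.full(outer.shape, LABEL_S, dtype=np.int8)
        labels[outer < betas[:, None] - eps] = LABEL_D
        labels[outer > betas[:, None] + eps] = LABEL_L

        # cheap vectorized prefilters implied by the arc rules:
        # >= 2 arcs of each polarity, each >= 2 long -> >= 4 d and >= 4 l
        # labels; arcs cover >= 8 ring pixels -> <= 8 s labels.
        n_d = (labels == LABEL_D).sum(axis=1)
        n_l = (labels == LABEL_L).sum(axis=1)
        n_s = 16 - n_d - n_l
        maybe = (n_d >= 4) & (n_l >= 4) & (n_s <= 8)

        keep_rows = []
        for i in np.nonzero(maybe)[0]:
            if outer_ring_test(labels[i]):
                keep_rows.append(i)
        stats.n_outer_pass.append(len(keep_rows))
        if not keep_rows:
            continue
        keep_rows = np.asarray(keep_rows)

        passing = []
        for i in keep_rows:
            r = response_strength(outer[i], labels[i], betas[i])
            passing.append((int(ys[i]), int(xs[i]), r))
        beta_by_pos = {(int(ys[i]), int(xs[i])): float(betas[i]) for i in keep_rows}

        survivors = nonmax_suppress(passing, octave.octave_index)
        for y, x, r in survivors:
            sx, sy = subpixel_refine(octave, y, x)
            ix, iy = to_input_coords(sx, sy, octave.octave_index)
            features.append(
                FeaturePoint(x=ix, y=iy, octave=octave.octave_index,
                             response=r, beta=beta_by_pos[(y, x)])
            )

    if not features:
        logger.warning("no saddle points detected")
    features.sort(key=lambda p: (p.octave, p.y, p.x))
    return (features, stats) if return_stats else features


def features_to_array(features: list[FeaturePoint]) -> np.ndarray:
    """(K, 5) float array with columns x, y, octave, response, beta."""
    if not features:
        return np.empty((0, 5))
    return np.array([[p.x, p.y, p.octave, p.response, p.beta] for p in features])
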