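import numpy as np
import pytest
from scipy import ndimage

from dsaddle.detector import (
    DetectorConfig,
    INNER_OFFSETS,
    LABEL_D,
    LABEL_L,
    LABEL_S,
    OUTER_OFFSETS,
    candidate_grid,
    detect,
    inner_ring_test,
    label_outer,
    nonmax_suppress,
    outer_ring_test,
    response_strength,
    sample_rings,
    subpixel_refine,
    to_input_coords,
)
from dsaddle.pyramid import DoGOctave, build_pyramid


def _octave(arr, index=0):
    arr = np.asarray(arr, dtype=np.float64)
    return DoGOctave(dog=arr, raw=arr.copy(), octave_index=index)


def _labels(text):
    return np.array([{"d": LABEL_D, "s": LABEL_S, "l": LABEL_L}[c] for c in text], dtype=np.int8)


class TestCandidateGrid:
    @pytest.mark.parametrize("size,expected", [(10, 16), (8, 4), (7, 1), (6, 0)])
    def test_lattice_size(self, size, expected, rng):
        oc = _octave(rng.uniform(0, 1, (size, size)))
        assert len(candidate_grid(oc)) == expected

    def test_bounds_leave_room_for_outer_ring(self, rng):
        oc = _octave(rng.uniform(0, 1, (12, 20)))
        grid = candidate_grid(oc)
        assert grid[:, 0].min() == 3 and grid[:, 0].max() == 12 - 4
        assert grid[:, 1].min() == 3 and grid[:, 1].max() == 20 - 4


class TestSampleRings:
    def test_constant_octave_uniform_rings(self):
        inner, outer = sample_rings(_octave(np.full((16, 16), 0.4)), 8, 8)
        assert len(inner) == 8 and len(outer) == 16
        assert np.ptp(inner) == 0 and np.ptp(outer) == 0

    def test_outer_ring_is_radius3_digital_circle(self):
        # frozen enumeration of the 16-pixel Bresenham circle of radius 3
        expected = {
            (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
            (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
        }
        assert set(map(tuple, OUTER_OFFSETS)) == expected
        axial = [o for o in OUTER_OFFSETS if 0 in o]
        assert len(axial) == 4 and all(max(abs(a), abs(b)) == 3 for a, b in axial)

    def test_rotating_image_90_permutes_outer_ring_by_4(self, rng):
        img = rng.uniform(0, 1, (15, 15))
        oc = _octave(img)
        # rot90 counter-clockwise maps (y, x) -> (n-1-x, y)
        oc_rot = _octave(np.rot90(img))
        _, outer = sample_rings(oc, 7, 7)
        _, outer_rot = sample_rings(oc_rot, 7, 7)
        np.testing.assert_allclose(np.roll(outer, -4), outer_rot)

    def test_out_of_bounds_candidate_rejected(self):
        with pytest.raises(ValueError):
            sample_rings(_octave(np.zeros((16, 16))), 2, 8)


class TestInnerRingTest:
    def _inner(self, top, ne, right, se, bottom, sw, left, nw):
        return np.array([top, ne, right, se, bottom, sw, left, nw])

    def test_plus_shape_passes_with_median_beta(self):
        inner = self._inner(0.8, 0.5, 0.2, 0.5, 0.8, 0.5, 0.2, 0.5)
        res = inner_ring_test(inner)
        assert res.passed and res.shapes == frozenset({"+"})
        assert res.beta == pytest.approx(np.median([0.8, 0.8, 0.2, 0.2]))
        assert res.beta == pytest.approx(0.5)

    def test_uniform_ring_fails(self):
        res = inner_ring_test(np.full(8, 0.5))
        assert not res.passed and res.beta is None

    def test_both_shapes_use_all_eight_pixels(self):
        inner = self._inner(0.9, 0.8, 0.1, 0.2, 0.9, 0.8, 0.1, 0.2)
        res = inner_ring_test(inner)
        assert res.shapes == frozenset({"+", "x"})
        assert res.beta == pytest.approx(np.median(inner))

    def test_either_polarity_accepted(self):
        bright_axial = self._inner(0.9, 0.5, 0.1, 0.5, 0.9, 0.5, 0.1, 0.5)
        dark_axial = self._inner(0.1, 0.5, 0.9, 0.5, 0.1, 0.5, 0.9, 0.5)
        assert inner_ring_test(bright_axial).passed
        assert inner_ring_test(dark_axial).passed

    def test_beta_within_inner_range(self, rng):
        for _ in range(200):
            inner = rng.uniform(0, 1, 8)
            res = inner_ring_test(inner)
            if res.passed:
                assert inner.min() <= res.beta <= inner.max()


class TestLabelOuter:
    def test_truth_table_boundaries_inclusive_into_s(self):
        beta, eps = 0.5, 0.0010
        outer = np.array([beta, beta + eps, beta - eps, 0.4, 0.6])
        labels = label_outer(outer, beta, eps)
        assert labels.tolist() == [LABEL_S, LABEL_S, LABEL_S, LABEL_D, LABEL_L]

    def test_default_epsilon_example(self):
        assert label_outer(np.array([0.4]), beta=0.5)[0] == LABEL_D


class TestOuterRingTest:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("ddddllllddddllll", True),    # 4 alternating arcs of length 4
            ("ssssssssssssssss", False),   # no arcs at all
            ("dllllddddllllsss", False),   # length-1 arc and s-run of 3
            ("ddllddllddllddll", True),    # 8 arcs of length 2
            ("ddsslldssdllssdd", False),   # arc of length 1 after s removal
            ("dddddddddlllllll", False),   # single 9-long arc
            ("ddddddddllllllll", False),   # only one arc per polarity
            ("ddddsslllldddsll", True),    # s-runs of <= 2 tolerated
            ("dddlllsdddlllssl", False),   # trailing l arc breaks alternation
        ],
    )
    def test_arc_rules(self, pattern, expected):
        assert outer_ring_test(_labels(pattern)) is expected

    def test_short_cyclic_sequences_supported(self):
        assert outer_ring_test(_labels("ddllddll"))
        assert not outer_ring_test(_labels("dddddlll"))


class TestResponseStrength:
    def test_symmetric_contrast(self):
        beta = 0.5
        outer = np.array([0.3] * 8 + [0.7] * 8)
        labels = label_outer(outer, beta)
        assert response_strength(outer, labels, beta) == pytest.approx(0.4)

    def test_all_s_is_zero(self):
        outer = np.full(16, 0.5)
        labels = label_outer(outer, 0.5)
        assert response_strength(outer, labels, 0.5) == 0.0

    def test_linear_in_contrast(self):
        beta = 0.5
        o1 = np.array([0.4] * 8 + [0.6] * 8)
        o2 = np.array([0.3] * 8 + [0.7] * 8)
        l1, l2 = label_outer(o1, beta), label_outer(o2, beta)
        assert response_strength(o2, l2, beta) == pytest.approx(
            2 * response_strength(o1, l1, beta)
        )


class TestNonmaxSuppress:
    def test_isolated_point_survives(self):
        assert nonmax_suppress([(5, 5, 0.3)], 0) == [(5, 5, 0.3)]

    def test_adjacent_weaker_point_removed(self):
        pts = [(5, 5, 0.3), (5, 6, 0.5)]
        assert nonmax_suppress(pts, 0) == [(5, 6, 0.5)]

    def test_tie_keeps_lexicographically_smallest(self):
        pts = [(5, 6, 0.5), (5, 5, 0.5)]
        assert nonmax_suppress(pts, 0) == [(5, 5, 0.5)]

    def test_higher_octaves_pass_through(self):
        pts = [(5, 5, 0.3), (5, 6, 0.5)]
        assert nonmax_suppress(pts, 1) == pts


class TestSubpixelRefine:
    def test_symmetric_peak_stays_centered(self):
        d = np.zeros((9, 9))
        d[4, 4] = 1.0
        d[3:6, 3:6] += 0.2
        x, y = subpixel_refine(_octave(d), 4, 4)
        assert (x, y) == pytest.approx((4.0, 4.0))

    def test_1d_parabola_vertex(self):
        # values (0.2, 0.5, 0.4) along x: vertex at (a-c)/(2(a-2b+c)) = +0.25
        d = np.tile(np.array([0.0, 0.2, 0.5, 0.4, 0.0]), (5, 1))
        x, y = subpixel_refine(_octave(d), 2, 2)
        assert x == pytest.approx(2.25)
        assert y == pytest.approx(2.0)

    def test_flat_neighborhood_degenerate_fallback(self):
        x, y = subpixel_refine(_octave(np.full((7, 7), 0.5)), 3, 3)
        assert (x, y) == (3.0, 3.0)

    def test_offsets_clamped_to_half_pixel(self, rng):
        for _ in range(50):
            oc = _octave(rng.uniform(0, 1, (7, 7)))
            x, y = subpixel_refine(oc, 3, 3)
            assert abs(x - 3) <= 0.5 and abs(y - 3) <= 0.5


class TestCoordinateLifting:
    def test_octave0_identity(self):
        assert to_input_coords(10.5, 3.25, 0) == (10.5, 3.25)

    def test_octave2_scales_by_4(self):
        assert to_input_coords(10, 20, 2) == (40, 80)


class TestDetect:
    def test_constant_image_yields_nothing(self):
        assert detect(np.full((64, 64), 0.5)) == []

    @staticmethod
    def _disc_with_vessels(contrasts, size=128):
        """Bright disc on mid background crossed by horizontal dark vessels."""
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.full((size, size), 0.45)
        c = size / 2
        img[(yy - c) ** 2 + (xx - c) ** 2 <= (0.38 * size) ** 2] = 0.75
        rows = [int(r * size) for r in np.linspace(0.3, 0.7, len(contrasts) + 2)[1:-1]]
        for contrast, r in zip(contrasts, rows):
            img[r - 1 : r + 2, :] -= contrast
        return np.clip(img, 0, 1), rows

    def test_detects_on_vessel_centerline(self):
        # one dark vessel (width 3, contrast 0.4) crossing a bright disc
        img, (row,) = self._disc_with_vessels([0.4])
        pts = detect(img)
        assert any(abs(p.y - row) <= 2.0 for p in pts)

    def test_hits_both_high_and_low_contrast_vessels(self):
        img, rows = self._disc_with_vessels([0.45, 0.1])
        pts = detect(img)
        # vicinity of the width-3 vessel at DoG scale: centerline +- 4 px
        for row in rows:
            assert any(abs(p.y - row) <= 4.0 for p in pts)

    @pytest.mark.parametrize("seed", [2, 5, 8])
    def test_contrast_increase_gains_vessel_detections(self, seed):
        # fixed-seed phantom, all vessels at one contrast: the high-contrast
        # version never yields fewer on-vessel detections than the faint one
        from dsaddle import PhantomConfig, generate_fundus

        counts = []
        for contrast in (0.08, 0.45):
            cfg = PhantomConfig(
                size=160, seed=seed, n_vessels=3, vessel_contrast_range=(contrast, contrast)
            )
            img, mask = generate_fundus(cfg)
            dist = ndimage.distance_transform_edt(~mask)
            pts = detect(img)
            counts.append(
                sum(
                    1
                    for p in pts
                    if p.octave == 0 and dist[int(round(p.y)), int(round(p.x))] <= 2.5
                )
            )
        assert counts[0] <= counts[1]

    def test_detections_respect_octave_bounds(self, small_phantom):
        img, _ = small_phantom
        pts = detect(img)
        pyr = build_pyramid(img)
        for p in pts:
            f = 2 ** p.octave
            n, m = pyr.octaves[p.octave].shape
            ox, oy = p.x / f, p.y / f
            assert 3 - 0.5 <= ox <= m - 4 + 0.5
            assert 3 - 0.5 <= oy <= n - 4 + 0.5

    def test_deterministic(self, small_phantom):
        img, _ = small_phantom
        assert detect(img) == detect(img)

    def test_rotation_covariance_90deg(self, small_phantom):
        img, _ = small_phantom
        n = img.shape[0]
        pts = detect(img)
        pts_rot = detect(np.ascontiguousarray(np.rot90(img)))
        # rot90 CCW maps (x, y) -> (y, n-1-x); compare octave-0 sets
        a = np.array([[p.y, n - 1 - p.x] for p in pts if p.octave == 0])
        b = np.array([[p.x, p.y] for p in pts_rot if p.octave == 0])
        border = 8
        core = a[(a[:, 0] > border) & (a[:, 0] < n - border)
                 & (a[:, 1] > border) & (a[:, 1] < n - border)]
        d = np.linalg.norm(core[:, None, :] - b[None, :, :], axis=2).min(axis=1)
        assert np.median(d) <= 1.0
        assert (d <= 1.0).mean() >= 0.9

    def test_stats_account_for_all_candidates(self, small_phantom):
        img, _ = small_phantom
        _, stats = detect(img, return_stats=True)
        assert len(stats.n_candidates) == 4
        assert all(p <= c for p, c in zip(stats.n_inner_pass, stats.n_candidates))
        assert all(o <= p for o, p in zip(stats.n_outer_pass, stats.n_inner_pass))
        assert 0.0 <= stats.inner_rejection_fraction <= 1.0
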