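import numpy as np
import pytest

from gaitgaze.aoi import (
    Trapezoid,
    dwell_time,
    filter_to_tracking_range,
    fit_trapezoid,
    gaze_aoi_distance,
)
from gaitgaze.io import AoiTrack

from conftest import make_recording


def brute_force_distance(point, corners, step=0.004):
    """Independent oracle: distance to a densely sampled filled quadrilateral
    (boundary sampling plus an even-odd inside test)."""
    px, py = point
    # inside test by ray casting
    inside = False
    n = len(corners)
    for i in range(n):
        x1, y1 = corners[i]
        x2, y2 = corners[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xin = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xin:
                inside = not inside
    if inside:
        return 0.0
    best = np.inf
    for i in range(n):
        a = np.asarray(corners[i], float)
        b = np.asarray(corners[(i + 1) % n], float)
        ts = np.arange(0.0, 1.0 + step, step)
        pts = a + ts[:, None] * (b - a)
        best = min(best, np.min(np.hypot(pts[:, 0] - px, pts[:, 1] - py)))
    return best


class TestFitTrapezoid:
    def test_axis_aligned_rectangle_exact(self):
        mask = np.zeros((40, 60), bool)
        mask[10:31, 5:51] = True
        trap = fit_trapezoid(mask)
        expect = {(5.0, 10.0), (50.0, 10.0), (50.0, 30.0), (5.0, 30.0)}
        assert {tuple(c) for c in trap.corners} == expect

    def test_perspective_skewed_quad_within_one_pixel(self):
        from skimage.draw import polygon
        true = np.array([[12.0, 8.0], [52.0, 12.0], [47.0, 38.0], [7.0, 33.0]])
        mask = np.zeros((50, 64), bool)
        rr, cc = polygon(true[:, 1], true[:, 0], mask.shape)
        mask[rr, cc] = True
        trap = fit_trapezoid(mask)
        for est in trap.corners:
            assert np.min(np.hypot(*(true - est).T)) <= 1.5

    def test_degenerate_mask_raises(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 3:6] = True
        with pytest.raises(ValueError):
            fit_trapezoid(mask)


class TestDistance:
    def test_inside_is_zero(self):
        trap = Trapezoid([(-2, -2), (2, -2), (2, 2), (-2, 2)])
        assert gaze_aoi_distance((0.5, -1.0), trap) == 0.0
        assert gaze_aoi_distance((2.0, 2.0), trap) == 0.0   # boundary

    def test_three_four_five(self):
        trap = Trapezoid([(0, 0), (-4, 0), (-4, -4), (0, -4)])
        assert gaze_aoi_distance((3.0, 4.0), trap) == pytest.approx(5.0)

    def test_matches_grid_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            base = rng.uniform(-20, 20, 2)
            quad = base + np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) \
                * rng.uniform(0.5, 6.0, (4, 1)) \
                + rng.uniform(-0.4, 0.4, (4, 2))
            try:
                trap = Trapezoid(quad)
            except ValueError:
                continue
            p = rng.uniform(-30, 30, 2)
            d_fast = gaze_aoi_distance(tuple(p), trap)
            d_slow = brute_force_distance(tuple(p), quad)
            assert d_fast == pytest.approx(d_slow, abs=0.01)

    def test_triangle_inequality_against_interior_point(self, rng):
        trap = Trapezoid([(-3, -2), (4, -3), (5, 3), (-4, 2)])
        centroid = trap.corners.mean(axis=0)
        for _ in range(50):
            p = rng.uniform(-20, 20, 2)
            d = gaze_aoi_distance(tuple(p), trap)
            assert d <= np.hypot(*(p - centroid)) + 1e-9


class TestRangeFilter:
    trap_in = Trapezoid([(-5, -5), (5, -5), (5, 5), (-5, 5)])
    trap_out = Trapezoid([(-5, -25), (5, -25), (5, -10), (-5, -10)])

    def test_gaze_out_of_horizontal_range_excluded(self):
        keep = filter_to_tracking_range(np.array([[40.0, 0.0]]), [self.trap_in])
        assert not keep[0]

    def test_trapezoid_corner_out_of_vertical_range_excluded(self):
        keep = filter_to_tracking_range(np.array([[0.0, 0.0]]), [self.trap_out])
        assert not keep[0]

    def test_everything_inside_kept(self):
        keep = filter_to_tracking_range(np.array([[0.0, 0.0]]), [self.trap_in])
        assert keep[0]

    def test_infinite_range_is_identity(self, rng):
        pts = rng.uniform(-80, 80, (20, 2))
        traps = [Trapezoid([(x - 1, -1), (x + 1, -1), (x + 1, 1), (x - 1, 1)])
                 for x in pts[:, 0]]
        keep = filter_to_tracking_range(pts, traps, (np.inf, np.inf))
        assert keep.all()


def build_track(rec, offsets, conf=0.95, frame_rate=30.0):
    """AOI track with 2x2-degree squares displaced from gaze by offsets."""
    ts = np.arange(rec.t[0], rec.t[-1], 1 / frame_rate)
    idx = np.clip(np.searchsorted(rec.t, ts), 0, len(rec) - 1)
    corners = []
    for k, i in enumerate(idx):
        off = offsets[k % len(offsets)]
        cx, cy = rec.x[i] + off[0], rec.y[i] + off[1]
        corners.append([[cx - 1, cy - 1], [cx + 1, cy - 1],
                        [cx + 1, cy + 1], [cx - 1, cy + 1]])
    return AoiTrack(ts, np.array(corners),
                    np.full(ts.size, conf, dtype=float))


class TestDwell:
    def test_never_near_gives_zero(self, rng):
        rec = make_recording(rng.normal(0, 1, 600), rng.normal(0, 1, 600))
        track = build_track(rec, [(8.0, 0.0)])
        res = dwell_time(rec, track)
        assert res.dwell_fraction == 0.0
        assert res.mean_distance == pytest.approx(7.0, abs=0.3)

    def test_always_inside_gives_one_and_zero_distance(self, rng):
        # slowly drifting gaze so the 30 Hz AOI frames stay centred on it
        x = np.cumsum(rng.normal(0, 0.01, 600))
        rec = make_recording(x, np.zeros(600))
        track = build_track(rec, [(0.0, 0.0)])
        res = dwell_time(rec, track)
        assert res.dwell_fraction == pytest.approx(1.0, abs=0.02)
        assert res.mean_distance == pytest.approx(0.0, abs=0.05)

    def test_fraction_monotone_in_threshold(self, rng):
        rec = make_recording(rng.normal(0, 3, 2000), rng.normal(0, 3, 2000))
        track = build_track(rec, [(0.0, 0.0), (2.5, 0.0), (4.5, 0.0),
                                  (9.0, 0.0)])
        fracs = [dwell_time(rec, track, threshold=th).dwell_fraction
                 for th in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_subthreshold_confidence_rejected(self, rng):
        rec = make_recording(rng.normal(0, 1, 600), rng.normal(0, 1, 600))
        track = build_track(rec, [(0.0, 0.0)], conf=0.5)
        with pytest.raises(ValueError, match="confidence"):
            dwell_time(rec, track)
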