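import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitgaze.metrics import (
    cardinal_oblique_ratio,
    direction_histogram,
    heatmap,
    sample_velocities,
    summarize_gaze,
    tshape_ratio,
    velocity_histogram,
)

from conftest import make_recording


class TestSummary:
    def test_constant_gaze(self):
        rec = make_recording(np.full(20, 3.0), np.full(20, -2.0))
        s = summarize_gaze(rec)
        assert (s.median_x, s.median_y) == (3.0, -2.0)
        assert (s.iqr_x, s.iqr_y) == (0.0, 0.0)
        assert s.median_reliable

    def test_uniform_vertical_iqr_is_half_range(self, rng):
        y = rng.uniform(0.0, 10.0, 200_000)
        rec = make_recording(np.zeros_like(y), y)
        s = summarize_gaze(rec)
        assert s.iqr_y == pytest.approx(5.0, abs=0.05)

    def test_offset_shifts_median_not_iqr(self, rng):
        x = rng.normal(0, 5, 500)
        y = rng.normal(0, 5, 500)
        a, b = 7.3, -4.1
        s0 = summarize_gaze(make_recording(x, y))
        s1 = summarize_gaze(make_recording(x + a, y + b))
        assert s1.median_x - s0.median_x == pytest.approx(a, abs=1e-9)
        assert s1.median_y - s0.median_y == pytest.approx(b, abs=1e-9)
        assert s1.iqr_x == pytest.approx(s0.iqr_x, abs=1e-9)

    def test_out_of_range_flags(self, rng):
        x = np.concatenate([np.full(60, 40.0), rng.normal(0, 1, 40)])
        rec = make_recording(x, np.zeros(100), world="RW",
                             tracking_range=(60.0, 46.0))
        s = summarize_gaze(rec)
        assert s.frac_out_right == 0.6
        assert not s.median_reliable

    @given(st.lists(st.floats(-80, 80), min_size=1, max_size=40),
           st.lists(st.floats(-80, 80), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_sort_based_oracle(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n])
        y = np.array(ys[:n])
        s = summarize_gaze(make_recording(x, y))

        def oracle_quartiles(v):
            v = np.sort(v)
            def q(p):
                h = (v.size - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, v.size - 1)
                return v[lo] + (h - lo) * (v[hi] - v[lo])
            return q(0.25), q(0.5), q(0.75)

        q1, q2, q3 = oracle_quartiles(x)
        assert s.median_x == pytest.approx(q2, abs=1e-9)
        assert s.iqr_x == pytest.approx(q3 - q1, abs=1e-9)


class TestTShape:
    def test_symmetric_distribution_ratio_one(self, rng):
        y = np.concatenate([-np.ones(500), np.ones(500)])
        x = np.tile(rng.normal(0, 3, 500), 2)
        assert tshape_ratio(make_recording(x, y)) == pytest.approx(1.0)

    def test_uniform_halves_converge_to_four(self, rng):
        n = 100_000
        y = np.concatenate([-np.ones(n // 2), np.ones(n // 2)])
        x = np.concatenate([rng.uniform(-20, 20, n // 2),
                            rng.uniform(-5, 5, n // 2)])
        assert tshape_ratio(make_recording(x, y)) == pytest.approx(4.0, rel=0.02)

    def test_zero_lower_iqr_flagged(self):
        y = np.concatenate([-np.ones(10), np.ones(10)])
        x = np.concatenate([np.arange(10.0), np.zeros(10)])
        with pytest.raises(ValueError, match="lower-half"):
            tshape_ratio(make_recording(x, y))


class TestDirections:
    def test_rightward_drift_all_mass_at_zero(self):
        x = np.arange(100) * 0.1
        h = direction_histogram(make_recording(x, np.zeros(100)))
        assert h.mass[0] == 1.0

    def test_diagonal_up_right_is_oblique_bin(self):
        x = np.arange(100) * 0.1
        y = -np.arange(100) * 0.1     # stored y down; moving up
        h = direction_histogram(make_recording(x, y))
        assert h.mass[1] == 1.0       # 45-degree bin

    def test_isotropic_uniform_within_3se(self, rng):
        n = 100_000
        ang = rng.uniform(0, 2 * np.pi, n)
        dx = np.cos(ang)
        dy = np.sin(ang)
        x = np.concatenate([[0], np.cumsum(dx)])
        y = np.concatenate([[0], np.cumsum(dy)])
        h = direction_histogram(make_recording(x, y))
        se = np.sqrt(0.125 * 0.875 / n)
        assert np.all(np.abs(h.mass - 0.125) < 3 * se)

    def test_unit_integral_and_no_moves_error(self, rng):
        x = rng.normal(0, 2, 1000)
        h = direction_histogram(make_recording(x, x))
        assert h.mass.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            direction_histogram(make_recording(np.zeros(10), np.zeros(10)))

    def test_uniform_histogram_ratio_one(self):
        from gaitgaze.metrics import DirectionHistogram
        h = DirectionHistogram(mass=np.full(8, 0.125), n_moves=800)
        assert cardinal_oblique_ratio(h) == 1.0
        with pytest.raises(ValueError):
            cardinal_oblique_ratio(
                DirectionHistogram(mass=np.array([0.25, 0, 0.25, 0, 0.25, 0,
                                                  0.25, 0]), n_moves=8))


class TestVelocities:
    def test_constant_speed(self):
        x = np.arange(10) * 1.0
        speed, vx, vy = sample_velocities(make_recording(x, np.zeros(10),
                                                         rate=10.0))
        np.testing.assert_allclose(speed, 10.0)
        np.testing.assert_allclose(vy, 0.0)

    def test_stationary_zero(self):
        speed, _, _ = sample_velocities(make_recording(np.zeros(10),
                                                       np.zeros(10)))
        np.testing.assert_array_equal(speed, 0.0)

    def test_no_velocity_across_blink(self):
        x = np.arange(11) * 1.0
        x[5] = np.nan
        speed, _, _ = sample_velocities(make_recording(x, np.zeros(11)))
        assert speed.size == 8    # pairs (4,5),(5,6) dropped

    def test_histogram_binning(self):
        vh = velocity_histogram(np.array([10.0]))
        assert vh.counts[4] == 1          # 8-16 bin
        vh = velocity_histogram(np.array([600.0]))
        assert vh.counts[10] == 1         # >512 bin
        vh = velocity_histogram(np.array([2.0]))
        assert vh.counts[2] == 1          # boundary joins 2-4 (left-closed)
        vh = velocity_histogram(np.array([0.5]))
        assert vh.counts[0] == 1


class TestHeatmap:
    def test_point_mass_preserved_by_smoothing(self):
        rec = make_recording(np.zeros(100), np.zeros(100))
        hm = heatmap(rec, smooth=False)
        assert hm.grid[50, 50] == 100
        assert hm.grid.sum() == 100
        hm_s = heatmap(rec, smooth=True)
        assert hm_s.grid.sum() == pytest.approx(100, rel=1e-9)

    def test_out_of_span_accumulates_in_edge_bin(self):
        rec = make_recording(np.full(5, 80.0), np.zeros(5))
        hm = heatmap(rec, smooth=False)
        assert hm.grid[50, 100] == 5

    def test_uniform_field_is_flat(self, rng):
        # ratio shrinks toward 1 as n grows; at this n the smoothed Poisson
        # fluctuations bound max/min by ~1.3
        n = 4_000_000
        rec = make_recording(rng.uniform(-50.5, 50.5, n),
                             rng.uniform(-50.5, 50.5, n))
        hm = heatmap(rec, smooth=True)
        assert hm.grid.max() / hm.grid.min() < 1.5

    def test_mass_equals_valid_count(self, rng):
        x = rng.normal(0, 10, 1000)
        x[:50] = np.nan
        rec = make_recording(x, rng.normal(0, 10, 1000))
        hm = heatmap(rec, smooth=False)
        assert hm.grid.sum() == 950

    def test_participant_normalization(self, rng):
        from gaitgaze.metrics import normalize_heatmaps
        maps = {
            "a": heatmap(make_recording(rng.normal(0, 2, 1000),
                                        rng.normal(0, 2, 1000))),
            "b": heatmap(make_recording(rng.normal(0, 2, 100),
                                        rng.normal(0, 2, 100))),
        }
        norm = normalize_heatmaps(maps, regularizer=0.05)
        peak = max(m.grid.max() for m in norm.values())
        assert peak == pytest.approx(1.05, abs=1e-9)
        assert min(m.grid.min() for m in norm.values()) >= 0.05


class TestOffsetInvariance:
    """Every metric except the medians ignores constant gaze offsets,
    mirroring the robustness argument for drift-contaminated recordings."""

    def test_full_suite_offset_invariant(self, rng):
        from gaitgaze.saccades import detect_saccades
        from gaitgaze.synth import default_params, simulate_session
        from gaitgaze.io import SectorMap

        plan = SectorMap([(0.0, 60.0, "corridor", 0)])
        rec, _, _ = simulate_session(default_params(9), "VR", plan,
                                     rng=np.random.default_rng(9))
        for a, b in [(13.7, -8.2), (-100.0, 55.5)]:
            shifted = rec.copy()
            shifted.x = rec.x + a
            shifted.y = rec.y + b
            s0, s1 = summarize_gaze(rec), summarize_gaze(shifted)
            assert abs(s1.iqr_x - s0.iqr_x) < 1e-10
            assert abs(s1.iqr_y - s0.iqr_y) < 1e-10
            assert abs(tshape_ratio(shifted) - tshape_ratio(rec)) < 1e-10
            h0, h1 = direction_histogram(rec), direction_histogram(shifted)
            assert np.abs(h0.mass - h1.mass).max() < 1e-10
            v0 = sample_velocities(rec)[0]
            v1 = sample_velocities(shifted)[0]
            assert np.abs(v0 - v1).max() < 1e-7
            assert len(detect_saccades(shifted)) == len(detect_saccades(rec))
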