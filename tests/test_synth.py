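import numpy as np
import pytest
from dataclasses import replace

from gaitgaze.io import SectorMap
from gaitgaze.synth import (
    default_params,
    default_sector_plan,
    simulate_aoi_track,
    simulate_cohort,
    simulate_horizon_frames,
    simulate_session,
)
from gaitgaze.metrics import summarize_gaze
from gaitgaze.preprocess import mark_invalid_samples


def quiet_params(seed=0, **cell_kw):
    """Defaults with every stochastic nuisance switched off."""
    p = default_params(seed)
    for k in p.cells:
        p.cells[k] = replace(p.cells[k], sigma_fix=0.0, sacc_rate_target=0.0,
                             **cell_kw)
    for w in p.worlds:
        p.worlds[w] = replace(p.worlds[w], drift_total=(0.0, 0.0),
                              valid_frac=1.0)
    return p


def test_quiet_session_is_constant_at_cell_mean():
    p = quiet_params()
    plan = SectorMap([(0.0, 30.0, "corridor", 0)])
    rec, _, truth = simulate_session(p, "VR", plan,
                                     rng=np.random.default_rng(0))
    cell = p.cell("VR", "corridor")
    assert np.allclose(rec.x, cell.mu_x)
    assert np.allclose(rec.y, cell.mu_y)
    assert truth.saccade_count == 0


def test_vr_sampling_is_nominal_120hz():
    rec, _, _ = simulate_session(default_params(0), "VR",
                                 rng=np.random.default_rng(0))
    assert rec.nominal_rate == 120.0
    assert np.allclose(np.diff(rec.t), 1.0 / 120.0)


def test_saccade_count_matches_renewal_expectation():
    """At a target rate r over duration T the injected count is ~ r*T with
    renewal-process fluctuations."""
    p = default_params(1)
    for k in p.cells:
        p.cells[k] = replace(p.cells[k], sacc_rate_target=2.0)
    plan = SectorMap([(0.0, 400.0, "corridor", 0)])
    rec, _, truth = simulate_session(p, "VR", plan,
                                     rng=np.random.default_rng(1))
    expected = 2.0 * 400.0
    # gamma(shape 2) renewal: count SD ~ sqrt(n/2); allow 4 sigma
    assert abs(truth.saccade_count - expected) < 4 * np.sqrt(expected / 2)
    # ground truth count equals the number of injected events exactly
    assert truth.saccade_count == len(truth.saccade_onsets)


def test_empty_sector_plan_raises():
    with pytest.raises(ValueError):
        simulate_session(default_params(0), "VR", SectorMap([]))


def test_blinks_zero_pupil_and_nan_gaze():
    rec, _, _ = simulate_session(default_params(2), "RW",
                                 rng=np.random.default_rng(2))
    bad = ~rec.valid
    assert bad.any()
    assert np.all(rec.pupil[bad] == 0.0)
    assert np.all(np.isnan(rec.x[bad]))


def test_valid_fraction_recovered_vr():
    """A VR session at valid_frac 0.995 measures ~99.5% valid (+-0.3 pp)."""
    fracs = []
    for seed in range(4):
        rec, _, _ = simulate_session(default_params(seed), "VR",
                                     rng=np.random.default_rng(seed))
        rec = mark_invalid_samples(rec)
        fracs.append(rec.valid.mean())
    assert abs(np.mean(fracs) - 0.995) < 0.003


def test_median_converges_to_mu_without_drift():
    p = default_params(5)
    for k in p.cells:
        p.cells[k] = replace(p.cells[k], cardinal_bias=0.0)
    for w in p.worlds:
        p.worlds[w] = replace(p.worlds[w], drift_total=(0.0, 0.0))
    plan = SectorMap([(0.0, 600.0, "corridor", 0)])
    rec, _, _ = simulate_session(p, "VR", plan, rng=np.random.default_rng(5))
    rec = mark_invalid_samples(rec)
    s = summarize_gaze(rec)
    cell = p.cell("VR", "corridor")
    assert abs(s.median_x - cell.mu_x) < 0.7
    assert abs(s.median_y - cell.mu_y) < 0.7


def test_cohort_is_within_subject_and_sized():
    cohort = simulate_cohort(8, default_params(0), 0, duration_scale=0.1)
    assert len(cohort) == 8
    for entry in cohort:
        assert set(entry["sessions"]) == {"VR", "RW"}
    with pytest.raises(ValueError):
        simulate_cohort(1, default_params(0), 0)


def test_cohort_mu_shift_moves_cell_truth():
    """An injected vertical offset on one cell shifts that cell's ground-truth
    median by the stated amount (construction check)."""
    base = default_params(4)
    base.subject_mu_sd = (0.0, 0.0)
    for w in base.worlds:
        base.worlds[w] = replace(base.worlds[w], drift_total=(0.0, 0.0))
    shift = 5.0
    c0 = simulate_cohort(3, base, 4, duration_scale=0.5)
    c1 = simulate_cohort(3, base, 4, duration_scale=0.5,
                         mu_y_shift={("RW", "descending"): shift})
    d0 = np.mean([e["sessions"]["RW"][2].sector_summary["descending"]["median_y"]
                  for e in c0])
    d1 = np.mean([e["sessions"]["RW"][2].sector_summary["descending"]["median_y"]
                  for e in c1])
    assert abs((d1 - d0) - shift) < 0.6
    # untouched cell unchanged in expectation
    u0 = np.mean([e["sessions"]["RW"][2].sector_summary["corridor"]["median_y"]
                  for e in c0])
    u1 = np.mean([e["sessions"]["RW"][2].sector_summary["corridor"]["median_y"]
                  for e in c1])
    assert abs(u1 - u0) < 0.6


def test_aoi_track_fraction_zero_means_never_on():
    from gaitgaze.aoi import Trapezoid, gaze_aoi_distance

    rec, _, _ = simulate_session(default_params(6), "RW",
                                 rng=np.random.default_rng(6))
    plan = default_sector_plan("RW")
    track, truth_intervals = simulate_aoi_track(
        rec, plan, on_aoi_fraction=0.0, rng=np.random.default_rng(6))
    assert truth_intervals == []
    idx = np.searchsorted(rec.t, track.frame_t)
    idx = np.clip(idx, 0, len(rec) - 1)
    for k in range(0, len(track.frame_t), 7):
        g = (rec.x[idx[k]], rec.y[idx[k]])
        if not np.isfinite(g).all():
            continue
        assert gaze_aoi_distance(g, Trapezoid(track.corners[k])) > 1.0


def test_aoi_confidence_threshold_empties_track():
    rec, _, _ = simulate_session(default_params(6), "RW",
                                 rng=np.random.default_rng(6))
    track, _ = simulate_aoi_track(rec, default_sector_plan("RW"),
                                  rng=np.random.default_rng(6))
    track.confidence[:] = 0.5
    assert len(track.above_confidence(0.9).frame_t) == 0


def test_horizon_frames_identical_without_shift_or_noise():
    frames, trace = simulate_horizon_frames(5, np.zeros(5), 0.0)
    assert np.array_equal(frames[0], frames[4])
    assert np.all(trace == 0)


def test_horizon_frames_step_shift_moves_image():
    trace = np.zeros(12)
    trace[10:] = 3.0
    frames, _ = simulate_horizon_frames(12, trace, 0.0)
    # integer 3-px shift: rows move down by 3
    np.testing.assert_allclose(frames[10][10:-10], frames[0][7:-13], atol=1e-12)
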