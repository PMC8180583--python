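"""Synthetic gaze sessions with known ground truth.

The generator emulates the statistical structure of binocular-sampled gaze
recorded while walking a fixed indoor route in two "worlds": a virtual
building viewed through an HMD (120 Hz eye tracker, 100x110 deg tracking
range) and the matching real building viewed through a mobile tracker
(60 Hz, 60x46 deg).  The route alternates corridors, ascending staircases
and descending staircases; gaze statistics differ by terrain (lower gaze on
descending stairs, wider horizontal scanning above the vertical median,
cardinal-biased movement directions) and by device (validity, drift,
saccade rate).

The gaze process is an alternating fixation/saccade renewal process:

* saccade onsets follow a gamma renewal process tuned to a per-cell target
  rate;
* each saccade either performs a *directional jump* (direction drawn near a
  cardinal axis with probability ``cardinal_bias``, amplitude gamma
  distributed, reflected at a soft spatial boundary so cardinal directions
  stay cardinal) or re-targets a fresh fixation point drawn from the cell's
  spatial distribution;
* the spatial distribution is Gaussian around ``(mu_x, mu_y)`` with the
  horizontal SD inflated by ``upper_lower_spread_ratio`` for points above
  the vertical centre, which produces T-shaped gaze maps;
* saccade trajectories follow a raised-cosine velocity profile whose
  duration grows with amplitude (main-sequence-like: larger saccades are
  faster at peak);
* measured gaze = true process + isotropic fixational noise + linear drift
  accumulating to ``drift_total`` at session end;
* blinks (pupil = 0, gaze NaN) arrive as a Poisson process whose rate is
  set so the expected valid fraction matches ``valid_frac``.

Every session is accompanied by a :class:`GroundTruth` carrying the exact
injected saccades, the noise-free process and its per-sector median/IQR, so
downstream estimators can be checked sample-for-sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import (
    AoiTrack,
    GazeRecording,
    HeadPoseTrack,
    SectorMap,
    NOMINAL_RATE_RW,
    NOMINAL_RATE_VR,
    TRACKING_RANGE_RW,
    TRACKING_RANGE_VR,
    SECTOR_LABELS,
)

__all__ = [
    "CellParams",
    "WorldParams",
    "GenParams",
    "GroundTruth",
    "default_params",
    "default_sector_plan",
    "simulate_session",
    "simulate_cohort",
    "simulate_aoi_track",
    "simulate_validation_grid",
    "simulate_horizon_frames",
]


@dataclass
class CellParams:
    """Gaze-process parameters for one world x sector cell."""

    mu_x: float = 0.0            # deg, cell median gaze, positive = right
    mu_y: float = 0.0            # deg, positive = down
    sigma_pos_x: float = 6.0     # deg, SD of fixation-target scatter
    sigma_pos_y: float = 5.0
    sigma_fix: float = 0.3       # deg, per-sample fixational/measurement noise
    fix_dur_shape: float = 2.0   # gamma shape of inter-saccade intervals
    sacc_rate_target: float = 2.0    # 1/s
    sacc_amp_mean: float = 4.5   # deg
    sacc_amp_shape: float = 5.0
    sacc_amp_min: float = 2.5    # deg, floor keeping jumps detector-visible
    cardinal_bias: float = 0.6   # P(directional jump near a cardinal axis)
    cardinal_jitter: float = 6.0  # deg of angular noise around the axis
    upper_lower_spread_ratio: float = 1.16


@dataclass
class WorldParams:
    """Device- and session-level parameters for one world."""

    rate_hz: float = NOMINAL_RATE_VR
    valid_frac: float = 0.995
    blink_dur_mean: float = 0.15     # s
    blink_dur_shape: float = 3.0
    dropout_dur_mean: float = 1.2    # s, extended tracking-loss episodes
    blink_budget_frac: float = 1.0   # share of invalid coverage from blinks
    drift_total: tuple[float, float] = (0.0, 0.0)   # deg at session end
    tracking_range: tuple[float, float] = TRACKING_RANGE_VR
    head_pitch_by_sector: dict = field(default_factory=dict)  # deg, + = down
    head_roll_by_sector: dict = field(default_factory=dict)   # deg, + = right
    head_noise_sd: tuple[float, float] = (2.0, 1.0)  # pitch, roll


@dataclass
class GenParams:
    """Full generator configuration: one CellParams per (world, sector) plus
    per-world device parameters and a master seed."""

    cells: dict = field(default_factory=dict)   # (world, sector) -> CellParams
    worlds: dict = field(default_factory=dict)  # world -> WorldParams
    subject_mu_sd: tuple[float, float] = (2.0, 3.0)   # between-subject offset SD
    subject_rate_sd: float = 0.0      # lognormal sigma on saccade rate
    seed: int = 0

    def cell(self, world: str, sector: str) -> CellParams:
        return self.cells[(world, sector)]


@dataclass
class GroundTruth:
    """Exact description of the injected process for one session."""

    saccade_onsets: np.ndarray
    saccade_offsets: np.ndarray
    saccade_count: int
    true_x: np.ndarray              # noise-free, drift-free process
    true_y: np.ndarray
    labels: np.ndarray              # per-sample sector label ('' outside)
    sector_summary: dict            # label -> dict(median_x, median_y, iqr_x, iqr_y)
    saccade_rate_by_sector: dict    # label -> injected events / valid seconds
    drift_total: tuple[float, float]
    head_pitch_by_sector: dict
    head_roll_by_sector: dict
    on_aoi_intervals: list = field(default_factory=list)   # (t0, t1) truth


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------

# Per-cell median gaze (deg; x positive right, y positive down) and saccade
# rates for the two worlds and three terrain types.  The
# upper_lower_spread_ratio values are calibrated once so that the *measured*
# cohort-mean T-shape ratios land at the study conditions (corridor 1.16 VR /
# 1.15 RW; ascending 1.27 / 1.58; descending 1.54 / 2.77): the measured ratio
# is an emergent, world-dependent monotone function of the parameter because
# the cardinal walk and in-flight samples dilute the upper/lower asymmetry.
_CELL_DEFAULTS = {
    ("VR", "corridor"): dict(mu_x=-2.62, mu_y=4.43, sacc_rate_target=1.64,
                             upper_lower_spread_ratio=1.137),
    ("VR", "ascending"): dict(mu_x=-1.92, mu_y=6.17, sacc_rate_target=2.28,
                              upper_lower_spread_ratio=1.232),
    ("VR", "descending"): dict(mu_x=-0.93, mu_y=15.16, sacc_rate_target=2.21,
                               upper_lower_spread_ratio=1.292),
    ("RW", "corridor"): dict(mu_x=2.40, mu_y=-4.15, sacc_rate_target=3.48,
                             upper_lower_spread_ratio=1.299),
    ("RW", "ascending"): dict(mu_x=2.69, mu_y=1.46, sacc_rate_target=3.63,
                              upper_lower_spread_ratio=1.565),
    ("RW", "descending"): dict(mu_x=2.49, mu_y=5.27, sacc_rate_target=3.27,
                               upper_lower_spread_ratio=3.014),
}

_WORLD_DEFAULTS = {
    "VR": dict(
        rate_hz=NOMINAL_RATE_VR, valid_frac=0.995, blink_dur_mean=0.15,
        drift_total=(4.53, 4.53),          # magnitude ~6.4 deg
        tracking_range=TRACKING_RANGE_VR,
        head_pitch_by_sector={"corridor": 0.0, "ascending": 0.55,
                              "descending": 14.6},
        head_roll_by_sector={"corridor": 0.0, "ascending": 0.34,
                             "descending": -0.27},
    ),
    "RW": dict(
        rate_hz=NOMINAL_RATE_RW, valid_frac=0.855, blink_dur_mean=0.25,
        blink_budget_frac=0.4, dropout_dur_mean=1.2,
        drift_total=(7.64, 7.64),          # magnitude ~10.8 deg
        tracking_range=TRACKING_RANGE_RW,
    ),
}

# Route composition: 6 corridors, 4 ascending stair segments, 2 descending,
# separated by short unclassified connecting areas (turns).  Total sector
# durations per world follow the recorded session lengths (corridors
# 167.5 s VR / 123 s RW; ascending 29.1 / 25.1 s; descending 23.1 / 24.3 s).
_ROUTE_ORDER = (
    "corridor", "corridor", "ascending", "ascending", "corridor",
    "descending", "corridor", "ascending", "ascending", "corridor",
    "descending", "corridor",
)
_SECTOR_TOTALS = {
    "VR": {"corridor": 167.5, "ascending": 29.1, "descending": 23.1},
    "RW": {"corridor": 123.0, "ascending": 25.1, "descending": 24.3},
}
_GAP_S = 2.0    # unclassified turn between consecutive sectors


def default_params(seed: int = 0) -> GenParams:
    """Generator configuration reproducing the study's conditions."""
    cells = {}
    for key, overrides in _CELL_DEFAULTS.items():
        cells[key] = CellParams(**overrides)
    worlds = {w: WorldParams(**kw) for w, kw in _WORLD_DEFAULTS.items()}
    # ~10% lognormal between-subject scatter on saccade rates, matching the
    # reported per-world SDs (0.35 and 0.18 /s)
    return GenParams(cells=cells, worlds=worlds, seed=seed,
                     subject_rate_sd=0.1)


def default_sector_plan(world: str = "VR",
                        duration_scale: float = 1.0) -> SectorMap:
    """The walking route as a sector map: 6 corridors, 4 ascending and 2
    descending stair segments with unclassified turns in between.

    ``duration_scale`` shrinks every interval proportionally, for quick
    simulations.
    """
    totals = _SECTOR_TOTALS[world]
    counts = {lab: _ROUTE_ORDER.count(lab) for lab in SECTOR_LABELS}
    per = {lab: duration_scale * totals[lab] / counts[lab] for lab in SECTOR_LABELS}
    t = 0.0
    intervals = []
    for k, lab in enumerate(_ROUTE_ORDER):
        if k > 0:
            intervals.append((t, t + _GAP_S * duration_scale, "unclassified", -1))
            t += _GAP_S * duration_scale
        intervals.append((t, t + per[lab], lab, k))
        t += per[lab]
    return SectorMap(intervals)


# ---------------------------------------------------------------------------
# Core gaze process
# ---------------------------------------------------------------------------

def _saccade_duration(amplitude: float) -> float:
    # main-sequence-like: ~20 ms base + 2.5 ms/deg
    return 0.02 + 0.0025 * amplitude


def _raised_cosine_fraction(tau: np.ndarray, T: float) -> np.ndarray:
    """Fraction of displacement completed at time tau into a saccade of
    duration T; velocity is a raised cosine (smooth, symmetric)."""
    u = np.clip(tau / T, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _reflect(value: float, lo: float, hi: float) -> float:
    # fold into [lo, hi]; preserves axis alignment of the incoming step
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2 * span)
    return lo + (span - abs(v - span))


#: refractory gap after a saccade before the next one can start, s
SACCADE_REFRACTORY = 0.08

_interval_scale_cache: dict = {}


def _calibrated_interval_scale(rate: float, shape: float, floor: float) -> float:
    """Gamma scale such that E[max(X, floor)] = 1/rate.

    The refractory floor truncates the renewal distribution from below and
    would otherwise inflate the mean interval; the scale is deflated by
    bisection so the injected saccade rate matches the target exactly.
    """
    key = (round(rate, 6), round(shape, 6), round(floor, 6))
    if key in _interval_scale_cache:
        return _interval_scale_cache[key]
    from scipy.stats import gamma as gamma_dist

    target_mean = 1.0 / rate
    if target_mean <= floor:
        _interval_scale_cache[key] = 1e-6
        return 1e-6

    def trunc_mean(theta: float) -> float:
        # E[max(X, m)] = m F_k(m) + k theta (1 - F_{k+1}(m))
        fk = gamma_dist.cdf(floor, shape, scale=theta)
        fk1 = gamma_dist.cdf(floor, shape + 1, scale=theta)
        return floor * fk + shape * theta * (1.0 - fk1)

    lo, hi = 1e-6, target_mean / shape
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if trunc_mean(mid) > target_mean:
            hi = mid
        else:
            lo = mid
    _interval_scale_cache[key] = hi
    return hi


def _draw_interval(cell: CellParams, rng: np.random.Generator,
                   minimum: float) -> float:
    floor = _saccade_duration(cell.sacc_amp_mean) + SACCADE_REFRACTORY
    theta = _calibrated_interval_scale(cell.sacc_rate_target,
                                       cell.fix_dur_shape, floor)
    iv = rng.gamma(cell.fix_dur_shape, theta)
    return max(iv, minimum)


def _draw_target(cur: np.ndarray, cell: CellParams,
                 rng: np.random.Generator) -> np.ndarray:
    r = cell.upper_lower_spread_ratio
    if rng.random() < cell.cardinal_bias:
        axis = rng.integers(4)
        theta = math.radians(90.0 * axis + rng.normal(0.0, cell.cardinal_jitter))
        amp = max(cell.sacc_amp_min,
                  rng.gamma(cell.sacc_amp_shape,
                            cell.sacc_amp_mean / cell.sacc_amp_shape))
        # screen y grows downward; direction 90 deg means gaze moving up.
        # Horizontal excursions above the vertical centre are widened by the
        # T-shape factor (scanning the surroundings), below it they stay
        # narrow (scanning the path); cardinal jumps remain cardinal.
        x_scale = r if cur[1] < cell.mu_y else 1.0
        cand_x = cur[0] + amp * math.cos(theta) * x_scale
        cand_y = cur[1] - amp * math.sin(theta)
        by = 3.5 * cell.sigma_pos_y
        y = _reflect(cand_y, cell.mu_y - by, cell.mu_y + by)
        # horizontal bounds widen above the vertical centre by the T-shape
        # factor, so the walk component carries the same upper/lower spread
        # asymmetry as the re-targeting component; axis-aligned reflection
        # keeps cardinal jumps cardinal
        bx = 3.5 * cell.sigma_pos_x * (r if y < cell.mu_y else 1.0)
        return np.array([_reflect(cand_x, cell.mu_x - bx, cell.mu_x + bx), y])
    y = cell.mu_y + cell.sigma_pos_y * rng.standard_normal()
    scale = r if y < cell.mu_y else 1.0
    x = cell.mu_x + cell.sigma_pos_x * scale * rng.standard_normal()
    return np.array([x, y])


def _iqr(a: np.ndarray) -> float:
    q1, q3 = np.percentile(a, [25, 75])
    return float(q3 - q1)


def simulate_session(
    params: GenParams,
    world: str,
    sector_plan: SectorMap | None = None,
    *,
    participant_id: str = "S1",
    rng: np.random.Generator | None = None,
    cell_overrides: dict | None = None,
    world_params: WorldParams | None = None,
) -> tuple[GazeRecording, HeadPoseTrack, GroundTruth]:
    """Simulate one participant's recording in one world.

    Returns the measured recording (noise + drift + blinks applied), the
    head-pose track sampled on the same clock, and the exact ground truth.
    ``cell_overrides`` maps sector label -> CellParams replacing the
    defaults for this session (used for per-subject random effects);
    ``world_params`` replaces the world-level defaults (e.g. a
    participant-specific drift vector).
    """
    if sector_plan is None:
        sector_plan = default_sector_plan(world)
    if not sector_plan.intervals:
        raise ValueError("sector_plan is empty")
    rng = rng or np.random.default_rng(params.seed)
    wp = world_params or params.worlds[world]

    t0 = min(iv[0] for iv in sector_plan.intervals)
    t_end = max(iv[1] for iv in sector_plan.intervals)
    dt = 1.0 / wp.rate_hz
    t = t0 + dt * np.arange(int(np.floor((t_end - t0) / dt)) + 1)
    n = t.size
    labels = sector_plan.label_of(t)

    cells = {lab: params.cell(world, lab) for lab in SECTOR_LABELS}
    if cell_overrides:
        cells.update(cell_overrides)

    def cell_at(time: float) -> CellParams:
        lab = sector_plan.label_of(np.array([time]))[0]
        if lab in cells:
            return cells[lab]
        # connecting areas keep the upcoming sector's statistics
        upcoming = [iv for iv in sector_plan.intervals
                    if iv[2] in cells and iv[1] > time]
        lab2 = min(upcoming, key=lambda iv: iv[0])[2] if upcoming else "corridor"
        return cells[lab2]

    # --- event schedule -----------------------------------------------------
    first_cell = cell_at(t0)
    cur = np.array([first_cell.mu_x, first_cell.mu_y])
    events: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    if any(c.sacc_rate_target > 0 for c in cells.values()):
        t_next = t0 + _draw_interval(first_cell, rng, 0.1)
        while t_next < t_end:
            cell = cell_at(t_next)
            if cell.sacc_rate_target <= 0:
                # skip ahead past this zero-rate region
                t_next += 0.5
                continue
            target = _draw_target(cur, cell, rng)
            amp = float(np.hypot(*(target - cur)))
            T_sac = _saccade_duration(amp)
            events.append((t_next, t_next + T_sac, cur.copy(), target.copy()))
            cur = target
            t_next = t_next + _draw_interval(cell, rng,
                                             T_sac + SACCADE_REFRACTORY)

    # --- sample the true process -------------------------------------------
    true_xy = np.empty((n, 2))
    pos = np.array([first_cell.mu_x, first_cell.mu_y])
    prev_end_idx = 0
    for onset, offset, p0, p1 in events:
        i0 = int(np.searchsorted(t, onset, side="left"))
        i1 = int(np.searchsorted(t, offset, side="left"))
        true_xy[prev_end_idx:i0] = pos
        if i1 > i0:
            f = _raised_cosine_fraction(t[i0:i1] - onset, offset - onset)
            true_xy[i0:i1] = p0 + f[:, None] * (p1 - p0)
        pos = p1
        prev_end_idx = i1
    true_xy[prev_end_idx:] = pos

    # --- measurement model --------------------------------------------------
    sigma_fix = np.empty(n)
    sigma_fix[:] = first_cell.sigma_fix
    for lab, cell in cells.items():
        sigma_fix[labels == lab] = cell.sigma_fix
    noise = rng.standard_normal((n, 2)) * sigma_fix[:, None]
    frac = (t - t0) / max(t_end - t0, 1e-12)
    drift = np.outer(frac, np.asarray(wp.drift_total))
    meas = true_xy + noise + drift

    # --- blinks / invalid samples ------------------------------------------
    # Invalid time is a Poisson union of short blinks and (for the mobile
    # tracker) extended tracking-loss dropouts; rates are set so the expected
    # coverage matches 1 - valid_frac exactly (M/G/infinity busy fraction).
    pupil = np.clip(rng.normal(3.5, 0.3, n), 0.5, None)
    invalid = np.zeros(n, dtype=bool)
    if wp.valid_frac < 1.0:
        budget = -math.log(wp.valid_frac)
        components = [(wp.blink_budget_frac * budget, wp.blink_dur_mean)]
        if wp.blink_budget_frac < 1.0:
            components.append(((1.0 - wp.blink_budget_frac) * budget,
                               wp.dropout_dur_mean))
        for share, dur_mean in components:
            rate = share / dur_mean
            n_ev = rng.poisson(rate * (t_end - t0))
            starts = rng.uniform(t0, t_end, n_ev)
            durs = rng.gamma(wp.blink_dur_shape, dur_mean / wp.blink_dur_shape,
                             n_ev)
            for s, d in zip(starts, durs):
                invalid |= (t >= s) & (t < s + d)
    pupil[invalid] = 0.0
    meas[invalid] = np.nan

    rec = GazeRecording(
        participant_id=participant_id, world=world,
        t=t, x=meas[:, 0], y=meas[:, 1], pupil=pupil, valid=~invalid,
        nominal_rate=wp.rate_hz, tracking_range=wp.tracking_range,
    )

    # --- head pose -----------------------------------------------------------
    pitch_by = wp.head_pitch_by_sector or {lab: 0.0 for lab in SECTOR_LABELS}
    roll_by = wp.head_roll_by_sector or {lab: 0.0 for lab in SECTOR_LABELS}
    pitch_base = np.zeros(n)
    roll_base = np.zeros(n)
    for lab in SECTOR_LABELS:
        pitch_base[labels == lab] = pitch_by.get(lab, 0.0)
        roll_base[labels == lab] = roll_by.get(lab, 0.0)
    smooth = 0.3 * wp.rate_hz   # ~300 ms transition between sectors
    pitch_base = ndimage.gaussian_filter1d(pitch_base, smooth, mode="nearest")
    roll_base = ndimage.gaussian_filter1d(roll_base, smooth, mode="nearest")

    def smooth_noise(sd: float) -> np.ndarray:
        w = ndimage.gaussian_filter1d(rng.standard_normal(n), 0.25 * wp.rate_hz,
                                      mode="nearest")
        s = w.std()
        return w / s * sd if s > 0 else w

    head = HeadPoseTrack(
        t=t,
        pitch=pitch_base + smooth_noise(wp.head_noise_sd[0]),
        roll=roll_base + smooth_noise(wp.head_noise_sd[1]),
        yaw=smooth_noise(5.0),
    )

    # --- ground truth ---------------------------------------------------------
    onsets = np.array([e[0] for e in events])
    offsets = np.array([e[1] for e in events])
    sector_summary = {}
    rate_truth = {}
    for lab in SECTOR_LABELS:
        m = labels == lab
        if not m.any():
            continue
        # summarise the noise-free process at the samples the measured
        # recording actually exposes (blink samples carry no gaze), so the
        # truth is comparable to the pipeline output sample-for-sample
        mv = m & ~invalid
        if not mv.any():
            mv = m
        sector_summary[lab] = dict(
            median_x=float(np.median(true_xy[mv, 0])),
            median_y=float(np.median(true_xy[mv, 1])),
            iqr_x=_iqr(true_xy[mv, 0]),
            iqr_y=_iqr(true_xy[mv, 1]),
        )
        valid_dur = dt * int((m & ~invalid).sum())
        if onsets.size:
            on_labels = sector_plan.label_of(onsets)
            n_ev = int((on_labels == lab).sum())
        else:
            n_ev = 0
        rate_truth[lab] = n_ev / valid_dur if valid_dur > 0 else np.nan

    truth = GroundTruth(
        saccade_onsets=onsets, saccade_offsets=offsets,
        saccade_count=len(events),
        true_x=true_xy[:, 0], true_y=true_xy[:, 1],
        labels=labels, sector_summary=sector_summary,
        saccade_rate_by_sector=rate_truth,
        drift_total=tuple(wp.drift_total),
        head_pitch_by_sector=dict(pitch_by), head_roll_by_sector=dict(roll_by),
    )
    return rec, head, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int,
    params: GenParams | None = None,
    seed: int | None = None,
    *,
    duration_scale: float = 1.0,
    mu_y_shift: dict | None = None,
) -> list[dict]:
    """Simulate a within-subject cohort: every participant walks the route in
    both worlds.

    Per-participant random effects add a common offset to every cell's
    ``(mu_x, mu_y)`` (SD :attr:`GenParams.subject_mu_sd`) and, optionally, a
    lognormal multiplier to saccade rates.  Each participant's headset drift
    keeps the configured endpoint *magnitude* but points in a random
    direction — within an individual all validation points share one offset,
    while across the cohort there is no directional bias.  ``mu_y_shift``
    maps ``(world, sector)`` to an additive vertical offset, for injecting
    known main effects or interactions.

    Returns a list of dicts with keys ``participant_id``, ``sessions`` (world
    -> (recording, head_track, truth)), ``plans`` (world -> SectorMap) and
    ``world_params`` (world -> the WorldParams actually used).
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 participants")
    params = params or default_params()
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    out = []
    for i, ss in enumerate(master.spawn(n)):
        rng = np.random.default_rng(ss)
        pid = f"S{i + 1}"
        dmu = rng.normal(0.0, params.subject_mu_sd)   # shared across all cells
        rate_mult = (math.exp(rng.normal(0.0, params.subject_rate_sd))
                     if params.subject_rate_sd > 0 else 1.0)
        sessions = {}
        plans = {}
        world_params = {}
        for world in ("VR", "RW"):
            overrides = {}
            for lab in SECTOR_LABELS:
                cell = params.cell(world, lab)
                shift = (mu_y_shift or {}).get((world, lab), 0.0)
                overrides[lab] = replace(
                    cell,
                    mu_x=cell.mu_x + dmu[0],
                    mu_y=cell.mu_y + dmu[1] + shift,
                    sacc_rate_target=cell.sacc_rate_target * rate_mult,
                )
            wp = params.worlds[world]
            mag = math.hypot(*wp.drift_total)
            if mag > 0:
                phi = rng.uniform(0.0, 2.0 * math.pi)
                wp = replace(wp, drift_total=(mag * math.cos(phi),
                                              mag * math.sin(phi)))
            plan = default_sector_plan(world, duration_scale)
            sessions[world] = simulate_session(
                params, world, plan, participant_id=pid, rng=rng,
                cell_overrides=overrides, world_params=wp,
            )
            plans[world] = plan
            world_params[world] = wp
        out.append({"participant_id": pid, "sessions": sessions,
                    "plans": plans, "world_params": world_params})
    return out


# ---------------------------------------------------------------------------
# AOI tracks
# ---------------------------------------------------------------------------

def simulate_aoi_track(
    rec: GazeRecording,
    smap: SectorMap,
    *,
    on_aoi_fraction: float = 0.035,
    frame_rate: float = 30.0,
    subthreshold_frac: float = 0.15,
    off_distance: float = 8.0,
    rng: np.random.Generator | None = None,
) -> tuple[AoiTrack, list[tuple[float, float]]]:
    """Emit a navigational-marker AOI track whose gaze dwell is controlled.

    During corridor segments the marker quadrilateral is visible at the frame
    rate; its apparent size grows as the walker approaches.  For a fraction
    ``on_aoi_fraction`` of total corridor time the quadrilateral is centred on
    the concurrent gaze sample (dwell), otherwise it is displaced so the gaze
    point stays > 1 deg outside it.  Detector confidence is high on dwell
    frames and drops below the 0.9 acceptance threshold for a fraction of the
    remaining frames (distant markers are harder to detect), giving the track
    a realistic sub-threshold tail.

    Returns the AOI track and the true on-AOI intervals.
    """
    rng = rng or np.random.default_rng(0)
    half_w, half_h = rec.tracking_range[0] / 2, rec.tracking_range[1] / 2
    frame_ts, corners, confs = [], [], []
    truth: list[tuple[float, float]] = []
    for c0, c1, lab, _ in smap.intervals:
        if lab != "corridor":
            continue
        ts = np.arange(c0, c1, 1.0 / frame_rate)
        if ts.size == 0:
            continue
        dur = c1 - c0
        # one contiguous dwell window per corridor
        on_dur = on_aoi_fraction * dur
        on_start = rng.uniform(c0, max(c0, c1 - on_dur)) if on_dur > 0 else c0
        if on_dur > 0:
            truth.append((on_start, on_start + on_dur))
        idx = np.clip(np.searchsorted(rec.t, ts), 0, len(rec) - 1)
        for ft, i in zip(ts, idx):
            approach = (ft - c0) / dur
            hw = 1.5 + 2.5 * approach      # half-width deg, grows on approach
            hh = 1.2 + 2.0 * approach
            gx, gy = rec.x[i], rec.y[i]
            on = on_dur > 0 and on_start <= ft < on_start + on_dur
            if on and np.isfinite(gx):
                cx = float(np.clip(gx, -half_w + hw, half_w - hw))
                cy = float(np.clip(gy, -half_h + hh, half_h - hh))
            else:
                ang = rng.uniform(0, 2 * np.pi)
                d = off_distance + max(hw, hh) + 1.0 + rng.uniform(0, 3.0)
                base_x = gx if np.isfinite(gx) else 0.0
                base_y = gy if np.isfinite(gy) else 0.0
                cx = float(np.clip(base_x + d * np.cos(ang),
                                   -half_w + hw, half_w - hw))
                cy = float(np.clip(base_y + d * np.sin(ang),
                                   -half_h + hh, half_h - hh))
                # clipping may pull the marker back toward gaze; push it out
                if np.isfinite(gx) and abs(cx - gx) < hw + 2 and abs(cy - gy) < hh + 2:
                    cx = float(np.clip(gx + (hw + 3.0) * np.sign(cx - gx + 1e-9),
                                       -half_w, half_w))
            # slight trapezoidal taper (narrower at the top, like a chair seen
            # from above eye level)
            taper = 0.75
            quad = np.array([
                [cx - hw * taper, cy - hh],
                [cx + hw * taper, cy - hh],
                [cx + hw, cy + hh],
                [cx - hw, cy + hh],
            ])
            if on:
                conf = rng.uniform(0.93, 1.0)
            elif rng.random() < subthreshold_frac:
                conf = rng.uniform(0.3, 0.9)
            else:
                conf = rng.uniform(0.91, 1.0)
            frame_ts.append(ft)
            corners.append(quad)
            confs.append(conf)
    track = AoiTrack(np.array(frame_ts), np.array(corners).reshape(-1, 4, 2),
                     np.array(confs))
    return track, truth


# ---------------------------------------------------------------------------
# Validation grids and horizon frames
# ---------------------------------------------------------------------------

def simulate_validation_grid(
    drift: tuple[float, float],
    *,
    spacing: tuple[float, float] = (11.5, 10.0),   # horizontal, vertical deg
    noise_sd: float = 0.2,
    rng: np.random.Generator | None = None,
):
    """End-of-session 3x3 validation grid readings: measured = true + drift
    + fixational noise.  Returns (true_points, measured_points), both (9, 2)."""
    rng = rng or np.random.default_rng(0)
    gx, gy = np.meshgrid(spacing[0] * np.array([-1, 0, 1]),
                         spacing[1] * np.array([-1, 0, 1]))
    true_pts = np.column_stack([gx.ravel(), gy.ravel()])
    meas = true_pts + np.asarray(drift) + rng.normal(0, noise_sd, (9, 2))
    return true_pts, meas


def simulate_horizon_frames(
    n_frames: int,
    shift_trace: np.ndarray,
    noise_sd: float = 0.0,
    *,
    shape: tuple[int, int] = (96, 128),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Textured grayscale frame stack translated vertically by a known trace.

    Each frame is a fixed base image (smoothed random texture with a strong
    horizontal luminance edge, emulating a far horizon through a window)
    shifted down by ``shift_trace[i]`` pixels (sub-pixel shifts via linear
    interpolation) plus i.i.d. Gaussian pixel noise.  Returns
    ``(frames, trace)`` with ``frames.shape == (n_frames, H, W)``.
    """
    shift_trace = np.asarray(shift_trace, dtype=float)
    if shift_trace.size != n_frames:
        raise ValueError("shift_trace length must equal n_frames")
    rng = rng or np.random.default_rng(0)
    h, w = shape
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    base = (base - base.min()) / (base.max() - base.min())
    # horizon: bright sky above, darker below, centred vertically
    rows = np.arange(h)[:, None]
    base = 0.6 * base + 0.4 / (1.0 + np.exp((rows - h / 2) / 1.5))
    frames = np.empty((n_frames, h, w))
    for i, s in enumerate(shift_trace):
        shifted = ndimage.shift(base, (s, 0.0), order=1, mode="nearest")
        frames[i] = shifted
        if noise_sd > 0:
            frames[i] = frames[i] + rng.normal(0, noise_sd, (h, w))
    return frames, shift_trace.copy()
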