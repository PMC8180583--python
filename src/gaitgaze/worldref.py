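"""World-referenced measures: horizon tracking, eye-in-world vertical gaze,
and head-pose statistics with a corridor zero reference.

Head-mounted gaze is natively *eye-in-head*: any offset between headset and
head contaminates absolute position.  Referencing the vertical gaze channel
to the visual horizon (tracked in the scene video) yields *eye-in-world*
coordinates in which such common-mode offsets cancel — the quantity that is
actually comparable between devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .io import GazeRecording, HeadPoseTrack, SectorMap, SECTOR_LABELS

__all__ = ["HorizonTrace", "track_horizon", "eye_in_world_vertical", "head_stats"]

KEYFRAME_CADENCE = 9    # one manual mark every 9 frames, propagated +/-4


@dataclass
class HorizonTrace:
    frame_t: np.ndarray            # or frame indices when no clock is given
    horizon_y: np.ndarray          # px (or deg after scaling)
    source: np.ndarray             # 'keyframe' | 'tracked'
    low_confidence: np.ndarray     # bool, correlation peak at search edge


def _parabolic_peak(values: np.ndarray, i: int) -> float:
    """Sub-sample peak position by parabola through three points around i."""
    if i <= 0 or i >= values.size - 1:
        return float(i)
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * (y0 - y2) / denom


def track_horizon(
    frames: np.ndarray,
    keyframe_marks: list[tuple[int, float]],
    *,
    patch_size: int = 64,
    search: int = 16,
    frame_t: np.ndarray | None = None,
) -> HorizonTrace:
    """Propagate manual horizon marks through a frame stack by normalised
    cross-correlation.

    Every marked keyframe anchors its +/-4 neighbours: a patch centred on
    the mark is matched against a vertical search band in each neighbour,
    and the correlation-peak displacement (parabolically refined to
    sub-pixel) moves the mark.  Keyframes pass through exactly.  Frames
    beyond the last keyframe's span attach to the nearest keyframe.
    """
    frames = np.asarray(frames, dtype=float)
    n, H, W = frames.shape
    marks = sorted(keyframe_marks)
    if not marks:
        raise ValueError("track_horizon: no keyframe marks")
    horizon = np.full(n, np.nan)
    source = np.full(n, "tracked", dtype=object)
    lowconf = np.zeros(n, dtype=bool)

    half = patch_size // 2
    cx = W // 2
    x0, x1 = max(0, cx - half), min(W, cx + half)

    for kf, y_mark in marks:
        horizon[kf] = y_mark
        source[kf] = "keyframe"
        yc = int(round(y_mark))
        p0, p1 = yc - half, yc + half
        p0c, p1c = max(0, p0), min(H, p1)
        patch = frames[kf, p0c:p1c, x0:x1]
        lo = kf - KEYFRAME_CADENCE // 2
        hi = kf + KEYFRAME_CADENCE // 2
        for j in range(max(0, lo), min(n, hi + 1)):
            if j == kf:
                continue
            # nearer keyframe wins; ties go to the earlier keyframe
            if not np.isnan(horizon[j]):
                continue
            b0 = max(0, p0c - search)
            b1 = min(H, p1c + search)
            band = frames[j, b0:b1, x0:x1]
            if band.shape[0] <= patch.shape[0]:
                horizon[j] = y_mark
                lowconf[j] = True
                continue
            corr = match_template(band, patch).ravel()
            i_pk = int(np.argmax(corr))
            if i_pk == 0 or i_pk == corr.size - 1:
                lowconf[j] = True
            shift = _parabolic_peak(corr, i_pk) + b0 - p0c
            horizon[j] = y_mark + shift

    # frames outside any keyframe's +/-4 span: copy nearest tracked value
    if np.isnan(horizon).any():
        idx = np.arange(n)
        known = ~np.isnan(horizon)
        horizon = np.interp(idx, idx[known], horizon[known])

    t = frame_t if frame_t is not None else np.arange(n, dtype=float)
    return HorizonTrace(frame_t=np.asarray(t, float), horizon_y=horizon,
                        source=source, low_confidence=lowconf)


def eye_in_world_vertical(
    rec: GazeRecording,
    trace_t: np.ndarray,
    horizon_y_deg: np.ndarray,
) -> np.ndarray:
    """Vertical gaze relative to the horizon, per gaze sample.

    Both inputs are in positive-down degrees; the result is
    ``gaze_y - horizon_y`` (positive = gaze below the horizon).  Each gaze
    sample takes the horizon value of the nearest frame in time (the gaze
    rate exceeds the frame rate on both devices).  Any constant added to
    both channels cancels, which is exactly why this referencing removes
    headset-placement offsets.
    """
    trace_t = np.asarray(trace_t, float)
    horizon_y_deg = np.asarray(horizon_y_deg, float)
    if trace_t.size == 0:
        raise ValueError("eye_in_world_vertical: empty horizon trace")
    # nearest-neighbour frame assignment
    pos = np.searchsorted(trace_t, rec.t)
    pos = np.clip(pos, 1, trace_t.size - 1) if trace_t.size > 1 else np.zeros(
        len(rec), dtype=int)
    if trace_t.size > 1:
        left = trace_t[pos - 1]
        right = trace_t[pos]
        pos = np.where(np.abs(rec.t - left) <= np.abs(right - rec.t), pos - 1, pos)
    return rec.y - horizon_y_deg[pos]


def head_stats(track: HeadPoseTrack, smap: SectorMap) -> dict:
    """Per-sector mean and IQR of pitch and roll, corridor-referenced.

    The headset's zero point depends on how it sits on the head, so the
    participant's mean corridor orientation serves as the zero reference;
    yaw is excluded (it is dominated by route turns, not posture).  Returns
    ``{sector: {pitch_mean, pitch_iqr, roll_mean, roll_iqr}}`` in degrees,
    pitch positive = downward.
    """
    labels = smap.label_of(track.t)
    corridor = labels == "corridor"
    if not corridor.any():
        raise ValueError("head_stats: no corridor samples to reference against")
    p0 = track.pitch[corridor].mean()
    r0 = track.roll[corridor].mean()
    out = {}
    for lab in SECTOR_LABELS:
        m = labels == lab
        if not m.any():
            continue
        p = track.pitch[m] - p0
        r = track.roll[m] - r0
        out[lab] = dict(
            pitch_mean=float(p.mean()),
            pitch_iqr=float(np.subtract(*np.percentile(p, [75, 25]))),
            roll_mean=float(r.mean()),
            roll_iqr=float(np.subtract(*np.percentile(r, [75, 25]))),
        )
    return out
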