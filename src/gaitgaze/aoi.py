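"""Area-of-interest geometry and dwell-time accounting.

AOIs are the trapezoid-shaped navigational markers (chairs with direction
arrows) detected per video frame — in the real world by an object detector
emitting 4 corner coordinates plus a confidence, in VR by re-rendering and
fitting the marker pixels with a quadrilateral.  Gaze "dwells" on an AOI
whenever its angular distance to the filled quadrilateral is at most 1
degree.  Because the VR tracking range is much larger than the real-world
one, VR frames are first harmonised to the real-world range (both gaze and
the whole quadrilateral must lie inside 60 x 46 deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .io import AoiTrack, GazeRecording, TRACKING_RANGE_RW

__all__ = [
    "Trapezoid",
    "fit_trapezoid",
    "gaze_aoi_distance",
    "filter_to_tracking_range",
    "dwell_time",
    "DwellResult",
]


@dataclass
class Trapezoid:
    """A simple quadrilateral in head-centred degrees, corners in consistent
    (counter-clockwise or clockwise) winding order."""

    corners: np.ndarray     # (4, 2)

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise ValueError("trapezoid needs exactly 4 (x, y) corners")
        poly = Polygon(self.corners)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("degenerate or self-intersecting quadrilateral")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.corners)


def fit_trapezoid(mask: np.ndarray, px_to_deg: float = 1.0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> Trapezoid:
    """Fit a quadrilateral to a binary marker mask.

    Corner candidates are the extreme points of the foreground under the
    four diagonal projections (min/max of x+y and x-y), which recovers the
    corners of an axis-aligned rectangle exactly and those of a moderately
    perspective-skewed quadrilateral to pixel accuracy.  Coordinates are
    pixel centres (col, row) scaled by ``px_to_deg`` and shifted by
    ``origin``.
    """
    mask = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 4:
        raise ValueError("mask has fewer than 4 foreground pixels")
    x = cols.astype(float)
    y = rows.astype(float)
    s = x + y
    d = x - y
    idx = [int(np.argmin(s)), int(np.argmax(d)), int(np.argmax(s)),
           int(np.argmin(d))]     # TL, TR, BR, BL
    pts = np.column_stack([x[idx], y[idx]]) * px_to_deg + np.asarray(origin)
    if len({tuple(p) for p in pts}) < 4:
        raise ValueError("degenerate mask: corner candidates coincide")
    return Trapezoid(pts)


def gaze_aoi_distance(point: tuple[float, float], trap: Trapezoid) -> float:
    """Angular distance (deg) from a gaze point to the *filled* quadrilateral:
    zero inside or on the boundary, else Euclidean distance to the nearest
    point of the region."""
    return float(trap.polygon.distance(Point(point)))


def filter_to_tracking_range(
    gaze_points: np.ndarray,
    traps: list[Trapezoid],
    tracking_range: tuple[float, float] = TRACKING_RANGE_RW,
) -> np.ndarray:
    """Keep only frames where the gaze point and the whole quadrilateral lie
    inside the (centred) tracking range.  Returns a boolean mask."""
    gaze_points = np.asarray(gaze_points, dtype=float)
    half_w, half_h = tracking_range[0] / 2.0, tracking_range[1] / 2.0
    keep = np.zeros(len(traps), dtype=bool)
    for i, (g, trap) in enumerate(zip(gaze_points, traps)):
        if not (np.isfinite(g).all() and abs(g[0]) <= half_w and abs(g[1]) <= half_h):
            continue
        c = trap.corners
        keep[i] = bool((np.abs(c[:, 0]) <= half_w).all()
                       and (np.abs(c[:, 1]) <= half_h).all())
    return keep


@dataclass
class DwellResult:
    dwell_fraction: float       # on-AOI time / total analysed time
    mean_distance: float        # deg, over frames with a visible AOI
    n_on: int
    n_aoi_frames: int
    n_total: int


def dwell_time(
    seg: GazeRecording,
    track: AoiTrack,
    *,
    threshold: float = 1.0,
    confidence: float = 0.9,
    harmonize_range: bool = False,
    tracking_range: tuple[float, float] = TRACKING_RANGE_RW,
) -> DwellResult:
    """Fraction of analysed time with gaze on the AOI, plus the mean
    gaze-to-AOI distance.

    Each gaze sample is matched to the nearest AOI observation in time; a
    sample is *on* the AOI when a confidence-accepted observation exists for
    its frame and the gaze-to-quadrilateral distance is at most
    ``threshold``.  The dwell denominator is the segment's full analysable
    time (dwell is reported as a share of time on the route), while the
    mean distance averages only over frames with a visible AOI.  With
    ``harmonize_range`` set (the VR case), frames where gaze or marker
    leave the real-world tracking range are not counted as AOI-visible.
    """
    acc = track.above_confidence(confidence)
    ok = seg.analyzable & np.isfinite(seg.x) & np.isfinite(seg.y)
    n_total = int(seg.analyzable.sum())
    if n_total == 0:
        raise ValueError("dwell_time: no analysable samples")
    if len(acc.frame_t) == 0:
        raise ValueError("dwell_time: no AOI observations above confidence")

    # nearest AOI frame per gaze sample, gated by half the median frame step
    ft = acc.frame_t
    max_gap = 0.5 * (np.median(np.diff(ft)) if ft.size > 1 else np.inf)
    pos = np.clip(np.searchsorted(ft, seg.t), 1, max(ft.size - 1, 1))
    if ft.size > 1:
        pos = np.where(np.abs(seg.t - ft[pos - 1]) <= np.abs(ft[pos] - seg.t),
                       pos - 1, pos)
    else:
        pos = np.zeros(len(seg), dtype=int)
    gap = np.abs(seg.t - ft[pos])
    has_aoi = ok & (gap <= max_gap * 1.001)

    traps = {}
    dists = []
    n_on = 0
    n_aoi = 0
    half_w, half_h = tracking_range[0] / 2.0, tracking_range[1] / 2.0
    for i in np.nonzero(has_aoi)[0]:
        k = int(pos[i])
        if k not in traps:
            try:
                traps[k] = Trapezoid(acc.corners[k])
            except ValueError:
                traps[k] = None
        trap = traps[k]
        if trap is None:
            continue
        g = (seg.x[i], seg.y[i])
        if harmonize_range:
            c = trap.corners
            inside = (abs(g[0]) <= half_w and abs(g[1]) <= half_h
                      and (np.abs(c[:, 0]) <= half_w).all()
                      and (np.abs(c[:, 1]) <= half_h).all())
            if not inside:
                continue
        d = gaze_aoi_distance(g, trap)
        dists.append(d)
        n_aoi += 1
        if d <= threshold:
            n_on += 1
    return DwellResult(
        dwell_fraction=n_on / n_total,
        mean_distance=float(np.mean(dists)) if dists else float("nan"),
        n_on=n_on, n_aoi_frames=n_aoi, n_total=n_total,
    )
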