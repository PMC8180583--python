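"""Descriptive gaze statistics: median/IQR summaries, T-shape ratio,
direction and velocity histograms, heatmaps.

Medians and IQRs are the paper-grade robust summaries for head-mounted gaze
data: the median tolerates samples that leave the tracker's calibrated
range (their side is still known even if their exact position is not, so
they can be counted on the correct side of the median), and the IQR is
additionally immune to the constant offsets produced by headset slippage.

Conventions
-----------
* Stored gaze ``y`` grows downward.  Movement *directions* are reported in
  the conventional mathematical frame (0 deg = rightward, 90 deg = upward
  gaze movement), so the vertical displacement sign is flipped before
  binning.
* Quantiles use linear interpolation (numpy default).
* Direction bins are 45-degree wedges centred on the cardinal and oblique
  axes, left-closed; velocity bins are octaves, left-closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import GazeRecording

__all__ = [
    "GazeSummary",
    "DirectionHistogram",
    "VelocityHistogram",
    "HeatMap",
    "summarize_gaze",
    "tshape_ratio",
    "direction_histogram",
    "cardinal_oblique_ratio",
    "sample_velocities",
    "velocity_histogram",
    "heatmap",
    "normalize_heatmaps",
    "VELOCITY_BIN_EDGES",
    "DIRECTION_BIN_CENTERS",
]

#: Octave velocity bin edges in deg/s; first bin is < 1, last is > 512.
VELOCITY_BIN_EDGES = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0,
                               128.0, 256.0, 512.0])
VELOCITY_BIN_LABELS = ("<1", "1-2", "2-4", "4-8", "8-16", "16-32", "32-64",
                       "64-128", "128-256", "256-512", ">512")

DIRECTION_BIN_CENTERS = np.arange(0.0, 360.0, 45.0)

#: Gaussian full width at half height of 1 bin, as a sigma in bins.
HEATMAP_FWHH_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GazeSummary:
    median_x: float
    median_y: float
    iqr_x: float
    iqr_y: float
    n_valid: int
    frac_out_left: float
    frac_out_right: float
    frac_out_up: float
    frac_out_down: float
    median_reliable: bool   # False when >50% of data is out of range on a side


@dataclass
class DirectionHistogram:
    """Unit-integral mass over eight 45-degree wedges; bin k is centred on
    ``45 * k`` degrees (0 = rightward, 90 = upward)."""

    mass: np.ndarray
    n_moves: int

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (8,):
            raise ValueError("direction histogram needs 8 bins")


@dataclass
class VelocityHistogram:
    counts: np.ndarray      # 11 octave bins
    n: int

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum() if self.n else self.counts


@dataclass
class HeatMap:
    """101x101 grid of 1-degree bins spanning +/-50 deg per axis; samples
    beyond the span accumulate in the outermost bins."""

    grid: np.ndarray
    extent: float = 50.0
    scale: float = 1.0          # normalisation divisor applied (1 = raw)
    smoothed: bool = False


def _valid_xy(seg: GazeRecording) -> tuple[np.ndarray, np.ndarray]:
    m = seg.analyzable & np.isfinite(seg.x) & np.isfinite(seg.y)
    return seg.x[m], seg.y[m]


def summarize_gaze(seg: GazeRecording) -> GazeSummary:
    """Componentwise median and IQR over valid samples, plus the fraction of
    samples outside the device tracking range on each side.

    Out-of-range samples stay in the computation: the tracker still reports
    the correct side, which is all the median and IQR need as long as no
    side holds more than 50% (median) / 25% (IQR) of the data.  The
    ``median_reliable`` flag trips when the 50% condition fails.
    """
    x, y = _valid_xy(seg)
    if x.size == 0:
        raise ValueError("summarize_gaze: no valid samples")
    half_w, half_h = seg.tracking_range[0] / 2, seg.tracking_range[1] / 2
    q1x, med_x, q3x = np.percentile(x, [25, 50, 75])
    q1y, med_y, q3y = np.percentile(y, [25, 50, 75])
    fl = float((x < -half_w).mean())
    fr = float((x > half_w).mean())
    fu = float((y < -half_h).mean())
    fd = float((y > half_h).mean())
    return GazeSummary(
        median_x=float(med_x), median_y=float(med_y),
        iqr_x=float(q3x - q1x), iqr_y=float(q3y - q1y),
        n_valid=int(x.size),
        frac_out_left=fl, frac_out_right=fr, frac_out_up=fu, frac_out_down=fd,
        median_reliable=max(fl, fr, fu, fd) < 0.5,
    )


def tshape_ratio(seg: GazeRecording, min_half: int = 4) -> float:
    """Horizontal-IQR ratio of the upper gaze half over the lower half.

    The data is split at the vertical median (ties at the median excluded);
    "upper" means gaze above the median, i.e. stored ``y`` *below* the
    median value.  Ratios above 1 indicate wider horizontal scanning in the
    upper visual field — the T-shaped pattern of navigational gaze.
    """
    x, y = _valid_xy(seg)
    if x.size < 2 * min_half:
        raise ValueError("tshape_ratio: too few valid samples")
    med_y = np.median(y)
    upper = y < med_y
    lower = y > med_y
    if upper.sum() < min_half or lower.sum() < min_half:
        raise ValueError("tshape_ratio: a half has too few samples")
    iqr_up = np.subtract(*np.percentile(x[upper], [75, 25]))
    iqr_lo = np.subtract(*np.percentile(x[lower], [75, 25]))
    if iqr_lo == 0:
        raise ValueError("tshape_ratio: lower-half horizontal IQR is zero")
    return float(iqr_up / iqr_lo)


def _movement_angles(seg: GazeRecording) -> np.ndarray:
    """Directions (deg, 0=right, 90=up) of non-zero displacements between
    consecutive valid samples."""
    ok = seg.analyzable & np.isfinite(seg.x) & np.isfinite(seg.y)
    both = ok[:-1] & ok[1:]
    dx = seg.x[1:][both] - seg.x[:-1][both]
    dy = seg.y[1:][both] - seg.y[:-1][both]
    nz = (dx != 0) | (dy != 0)
    # stored y grows downward; flip so 90 deg = upward movement
    return np.degrees(np.arctan2(-dy[nz], dx[nz])) % 360.0


def direction_histogram(seg: GazeRecording) -> DirectionHistogram:
    """Eight-wedge histogram of sample-to-sample movement directions,
    normalised to unit integral (the per-individual normalisation applied
    before any cohort averaging)."""
    ang = _movement_angles(seg)
    if ang.size == 0:
        raise ValueError("direction_histogram: no non-zero movements")
    # rotate so wedge k is [45k - 22.5, 45k + 22.5); left-closed
    idx = np.floor(((ang + 22.5) % 360.0) / 45.0).astype(int)
    mass = np.bincount(idx, minlength=8).astype(float)
    return DirectionHistogram(mass=mass / mass.sum(), n_moves=int(ang.size))


def cardinal_oblique_ratio(h: DirectionHistogram) -> float:
    """Total cardinal-wedge mass (0/90/180/270) over total oblique mass."""
    cardinal = h.mass[0::2].sum()
    oblique = h.mass[1::2].sum()
    if oblique == 0:
        raise ValueError("cardinal_oblique_ratio: zero oblique mass")
    return float(cardinal / oblique)


def sample_velocities(seg: GazeRecording):
    """Per-pair gaze speeds between neighbouring valid samples.

    Speed is the Euclidean displacement divided by the sample time
    difference; samples without a valid neighbour contribute nothing (no
    interpolation across blinks).  Returns ``(speed, speed_x, speed_y)`` in
    deg/s, with the component speeds as absolute values.
    """
    ok = seg.analyzable & np.isfinite(seg.x) & np.isfinite(seg.y)
    both = ok[:-1] & ok[1:]
    dt = seg.t[1:][both] - seg.t[:-1][both]
    if np.any(dt <= 0):
        raise ValueError("sample_velocities: non-positive time step")
    dx = np.abs(seg.x[1:][both] - seg.x[:-1][both])
    dy = np.abs(seg.y[1:][both] - seg.y[:-1][both])
    return np.hypot(dx, dy) / dt, dx / dt, dy / dt


def velocity_histogram(speeds: np.ndarray) -> VelocityHistogram:
    """Counts per octave bin (<1, 1-2, ..., 256-512, >512 deg/s); bin edges
    belong to the faster bin (left-closed)."""
    speeds = np.asarray(speeds, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("velocity_histogram: negative speed")
    idx = np.searchsorted(VELOCITY_BIN_EDGES, speeds, side="right")
    counts = np.bincount(idx, minlength=11).astype(float)
    return VelocityHistogram(counts=counts, n=int(speeds.size))


def heatmap(seg: GazeRecording, *, extent: float = 50.0,
            smooth: bool = True) -> HeatMap:
    """2D gaze histogram with 1-degree bins spanning +/-``extent`` degrees.

    Out-of-span samples accumulate in the outermost bins.  When ``smooth``
    is set, the grid is low-passed with a Gaussian of FWHH one bin
    (reflective boundaries, so total mass is conserved).  Grid axes are
    ``grid[row, col]`` = (y bin, x bin), y increasing downward.
    """
    x, y = _valid_xy(seg)
    nbins = int(2 * extent) + 1
    xi = np.clip(np.round(x + extent).astype(int), 0, nbins - 1)
    yi = np.clip(np.round(y + extent).astype(int), 0, nbins - 1)
    grid = np.zeros((nbins, nbins))
    np.add.at(grid, (yi, xi), 1.0)
    if smooth:
        grid = ndimage.gaussian_filter(grid, HEATMAP_FWHH_SIGMA, mode="reflect")
    return HeatMap(grid=grid, extent=extent, smoothed=smooth)


def normalize_heatmaps(maps: dict, regularizer: float = 0.0) -> dict:
    """Normalise a participant's heatmaps to a common range.

    All maps of one participant (typically one per sector within a world)
    are divided by the participant's single maximum bin value, preserving
    relative density across sectors.  ``regularizer`` adds the given
    fraction of the common scale to every bin (used for log display, where
    zero bins are otherwise undefined).
    """
    peak = max(float(m.grid.max()) for m in maps.values())
    if peak <= 0:
        peak = 1.0
    out = {}
    for key, m in maps.items():
        g = m.grid / peak + regularizer
        out[key] = HeatMap(grid=g, extent=m.extent, scale=peak, smoothed=m.smoothed)
    return out
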