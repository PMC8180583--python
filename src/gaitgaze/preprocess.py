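"""Validity marking, polynomial calibration, drift estimation, exclusions.

Calibration maps raw tracker readings onto a known 3x3 marker grid (spacing
11.5 deg horizontally, 10 deg vertically in the study's setup) via bivariate
polynomial least squares, one polynomial per output channel.  The same grid,
re-measured at session end, quantifies headset drift: the per-point offsets
``measured - true`` summarise how far the mapping has slipped.

Offsets of this kind leave every position-free measure (IQR, velocities,
direction histograms, saccade detection) untouched; only absolute medians
are affected.  That invariance is relied on throughout the package and is
enforced by property tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GazeRecording, SectorMap

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationGrid",
    "CalibrationModel",
    "DriftEstimate",
    "mark_invalid_samples",
    "fit_calibration",
    "apply_calibration",
    "estimate_drift",
    "apply_exclusion_windows",
]


@dataclass
class CalibrationGrid:
    """Nine target/reading pairs from a 3x3 calibration or validation grid."""

    true_points: np.ndarray        # (9, 2) degrees
    measured_points: np.ndarray    # (9, 2) raw units or degrees
    spacing: tuple[float, float] = (11.5, 10.0)

    def __post_init__(self) -> None:
        self.true_points = np.asarray(self.true_points, dtype=float)
        self.measured_points = np.asarray(self.measured_points, dtype=float)
        if self.true_points.shape != self.measured_points.shape:
            raise ValueError("true and measured point arrays must match in shape")
        if self.true_points.ndim != 2 or self.true_points.shape[1] != 2:
            raise ValueError("grid points must have shape (n, 2)")


@dataclass
class CalibrationModel:
    """Bivariate polynomial map raw -> degrees, one coefficient vector per
    output channel."""

    order: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    residual_rms: float

    def __call__(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = _design_matrix(np.asarray(x, float), np.asarray(y, float), self.order)
        return A @ self.coef_x, A @ self.coef_y


def _design_matrix(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """Full bivariate polynomial basis up to total degree ``order``."""
    cols = [np.ones_like(x)]
    for d in range(1, order + 1):
        for j in range(d + 1):
            cols.append(x ** (d - j) * y ** j)
    return np.column_stack(cols)


def mark_invalid_samples(rec: GazeRecording) -> GazeRecording:
    """Mark samples invalid where the pupil is absent (size zero) or gaze is
    non-finite; gaze on invalid samples is set to NaN."""
    valid = (rec.pupil > 0) & np.isfinite(rec.x) & np.isfinite(rec.y)
    out = rec.copy()
    out.valid = valid
    out.x = np.where(valid, out.x, np.nan)
    out.y = np.where(valid, out.y, np.nan)
    n_inv = int((~valid).sum())
    logger.info("mark_invalid_samples[%s/%s]: %d of %d samples invalid (%.1f%%)",
                rec.participant_id, rec.world, n_inv, len(rec),
                100.0 * n_inv / max(len(rec), 1))
    return out


def fit_calibration(grid: CalibrationGrid, order: int = 2) -> CalibrationModel:
    """Least-squares polynomial fit of measured grid readings onto the known
    marker positions.

    The default order-2 fit (full bivariate quadratic, 6 coefficients per
    channel) is the highest order safely constrained by 9 points.
    """
    n = grid.true_points.shape[0]
    n_coef = (order + 1) * (order + 2) // 2
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    if n_coef > n:
        raise ValueError(
            f"order {order} needs {n_coef} coefficients but only {n} points given"
        )
    A = _design_matrix(grid.measured_points[:, 0], grid.measured_points[:, 1], order)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient calibration design (collinear points?)")
    cx, *_ = np.linalg.lstsq(A, grid.true_points[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, grid.true_points[:, 1], rcond=None)
    resid = np.column_stack([A @ cx, A @ cy]) - grid.true_points
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return CalibrationModel(order=order, coef_x=cx, coef_y=cy, residual_rms=rms)


def apply_calibration(model: CalibrationModel, rec: GazeRecording) -> GazeRecording:
    """Map the gaze channels through a fitted calibration; validity untouched,
    NaN samples stay NaN."""
    out = rec.copy()
    finite = np.isfinite(rec.x) & np.isfinite(rec.y)
    if finite.any():
        mx, my = model(rec.x[finite], rec.y[finite])
        out.x[finite] = mx
        out.y[finite] = my
    return out


@dataclass
class DriftEstimate:
    mean_offset: tuple[float, float]   # componentwise mean, deg
    mean_magnitude: float              # mean Euclidean offset, deg
    per_point: np.ndarray              # (n, 2) offsets


def estimate_drift(end_grid: CalibrationGrid) -> DriftEstimate:
    """Headset drift from the end-of-session validation grid.

    Offsets are ``measured - true`` per point; the summary is the
    componentwise mean vector and the mean Euclidean magnitude, matching how
    endpoint drift is reported per participant.
    """
    if end_grid.true_points.shape[0] < 9:
        logger.warning("estimate_drift: only %d validation points (expected 9)",
                       end_grid.true_points.shape[0])
    offsets = end_grid.measured_points - end_grid.true_points
    mags = np.hypot(offsets[:, 0], offsets[:, 1])
    return DriftEstimate(
        mean_offset=(float(offsets[:, 0].mean()), float(offsets[:, 1].mean())),
        mean_magnitude=float(mags.mean()),
        per_point=offsets,
    )


def apply_exclusion_windows(rec: GazeRecording, smap: SectorMap) -> GazeRecording:
    """Flag samples inside disturbance windows as excluded.

    Excluded samples stay in the stream (audits can recount them) but are
    dropped from every analysis denominator via :attr:`GazeRecording.analyzable`.
    Overlapping windows are excluded once (union semantics).
    """
    out = rec.copy()
    mask = np.zeros(len(rec), dtype=bool)
    for t0, t1 in smap.exclusion_windows:
        mask |= (rec.t >= t0) & (rec.t < t1)
    out.excluded = out.excluded | mask
    logger.info("apply_exclusion_windows[%s/%s]: %d samples excluded",
                rec.participant_id, rec.world, int(mask.sum()))
    return out
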