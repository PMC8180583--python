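"""Data model and tabular I/O for gaze recordings, sector maps, head pose and AOI tracks.

Coordinate conventions used throughout the package
--------------------------------------------------
Gaze is expressed in head-centred degrees of visual field: ``x`` increases to
the right, ``y`` increases *downward* (gaze up has smaller y).  Time is in
seconds on a single per-recording clock shared by the gaze stream, the head
pose track and any AOI observations.

All tables are UTF-8 delimited text (CSV) with a one-line header, read and
written through :mod:`pandas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

#: Manufacturer-specified tracking extents (width°, height°), centred on (0, 0).
TRACKING_RANGE_VR = (100.0, 110.0)
TRACKING_RANGE_RW = (60.0, 46.0)

#: Nominal sampling rates of the two devices, Hz.
NOMINAL_RATE_VR = 120.0
NOMINAL_RATE_RW = 60.0

SECTOR_LABELS = ("corridor", "ascending", "descending")
SPECIAL_LABELS = ("excluded", "unclassified")

GAZE_COLUMNS = ("t", "x", "y", "pupil", "valid")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input violates a data-model invariant (e.g. non-monotone time)."""


@dataclass
class GazeRecording:
    """A timestamped monocular gaze stream for one participant in one world.

    Invalid samples (blinks, tracking loss) carry NaN gaze and ``valid=False``
    but are *retained* in the stream: duration bookkeeping (saccade-rate
    denominators, valid-fraction logging) needs them.
    """

    participant_id: str
    world: str                      # "VR" or "RW"
    t: np.ndarray                   # seconds, strictly increasing
    x: np.ndarray                   # degrees, positive = rightward
    y: np.ndarray                   # degrees, positive = downward
    pupil: np.ndarray               # arbitrary units, >= 0; 0 marks no pupil
    valid: np.ndarray               # bool per sample
    nominal_rate: float = NOMINAL_RATE_VR
    tracking_range: tuple[float, float] = TRACKING_RANGE_VR
    excluded: np.ndarray | None = None   # bool; True = disturbance window

    def __post_init__(self) -> None:
        if self.world not in ("VR", "RW"):
            raise ValidationError(f"world must be 'VR' or 'RW', got {self.world!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("x", "y", "pupil", "valid"):
            if getattr(self, name).size != n:
                raise ValidationError(f"column {name!r} length != time length")
        if n > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"time not strictly increasing at row {bad[0] + 1} "
                    f"(t={self.t[bad[0] + 1]!r})"
                )
        if self.excluded is None:
            self.excluded = np.zeros(n, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.size != n:
                raise ValidationError("excluded mask length != time length")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def analyzable(self) -> np.ndarray:
        """Samples that are valid and not inside an exclusion window."""
        return self.valid & ~self.excluded

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def copy(self) -> "GazeRecording":
        return replace(
            self,
            t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            pupil=self.pupil.copy(), valid=self.valid.copy(),
            excluded=self.excluded.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "x": self.x, "y": self.y,
                "pupil": self.pupil, "valid": self.valid.astype(int),
            }
        )


@dataclass
class SectorMap:
    """Labelled half-open time intervals ``[t_start, t_end)`` over a recording.

    Labels are the three terrain types plus ``excluded`` (disturbance windows,
    which subtract from any terrain label) and ``unclassified`` (connecting
    areas).  Terrain/unclassified intervals must not overlap each other;
    ``excluded`` windows may overlap anything.
    """

    intervals: list[tuple[float, float, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = set(SECTOR_LABELS) | set(SPECIAL_LABELS)
        cleaned = []
        for iv in self.intervals:
            t0, t1, label = float(iv[0]), float(iv[1]), str(iv[2])
            idx = int(iv[3]) if len(iv) > 3 else len(cleaned)
            if label not in allowed:
                raise ValidationError(f"unknown sector label {label!r}")
            if not t1 > t0:
                raise ValidationError(f"empty interval [{t0}, {t1}) for {label!r}")
            cleaned.append((t0, t1, label, idx))
        spans = sorted((c[0], c[1]) for c in cleaned if c[2] != "excluded")
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValidationError(
                    f"overlapping sector intervals: [{a0}, {a1}) and [{b0}, {b1})"
                )
        self.intervals = cleaned

    def with_label(self, label: str) -> list[tuple[float, float, str, int]]:
        return [iv for iv in self.intervals if iv[2] == label]

    @property
    def exclusion_windows(self) -> list[tuple[float, float]]:
        return [(t0, t1) for t0, t1, lab, _ in self.intervals if lab == "excluded"]

    def label_of(self, t: np.ndarray) -> np.ndarray:
        """Vector of labels ('' where no interval covers the sample)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for t0, t1, lab, _ in self.intervals:
            if lab == "excluded":
                continue
            out[(t >= t0) & (t < t1)] = lab
        for t0, t1 in self.exclusion_windows:
            out[(t >= t0) & (t < t1)] = "excluded"
        return out


@dataclass
class HeadPoseTrack:
    """Headset orientation over time (VR only): pitch positive = downward,
    roll positive = rightward tilt."""

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)


@dataclass
class AoiTrack:
    """Per-frame quadrilateral AOI observations with detector confidence.

    ``corners`` has shape (n_frames, 4, 2) in head-centred degrees.
    """

    frame_t: np.ndarray
    corners: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.frame_t = np.asarray(self.frame_t, dtype=float)
        self.corners = np.asarray(self.corners, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.corners.ndim != 3 or self.corners.shape[1:] != (4, 2):
            raise ValidationError("AOI corners must have shape (n, 4, 2)")

    def above_confidence(self, threshold: float = 0.9) -> "AoiTrack":
        keep = self.confidence > threshold
        return AoiTrack(self.frame_t[keep], self.corners[keep], self.confidence[keep])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gaze_table(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    participant_id: str = "unknown",
    world: str = "VR",
    nominal_rate: float | None = None,
    tracking_range: tuple[float, float] | None = None,
) -> GazeRecording:
    """Read a delimited gaze table into a :class:`GazeRecording`.

    Parameters
    ----------
    schema
        Optional mapping from required column names (``t,x,y,pupil,valid``) to
        the names used in the file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    schema = dict(schema or {})
    cols = {}
    for name in GAZE_COLUMNS:
        src = schema.get(name, name)
        if src not in df.columns:
            raise SchemaError(f"required column {name!r} (file column {src!r}) missing")
        cols[name] = df[src]
    t = pd.to_numeric(cols["t"], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(t)
    n_dropped = int((~keep).sum())
    if n_dropped:
        import logging
        logging.getLogger(__name__).info(
            "read_gaze_table: dropped %d rows with non-finite time", n_dropped
        )
    return GazeRecording(
        participant_id=participant_id,
        world=world,
        t=t[keep],
        x=cols["x"].to_numpy(dtype=float)[keep],
        y=cols["y"].to_numpy(dtype=float)[keep],
        pupil=cols["pupil"].to_numpy(dtype=float)[keep],
        valid=cols["valid"].to_numpy()[keep].astype(bool),
        nominal_rate=nominal_rate
        or (NOMINAL_RATE_VR if world == "VR" else NOMINAL_RATE_RW),
        tracking_range=tracking_range
        or (TRACKING_RANGE_VR if world == "VR" else TRACKING_RANGE_RW),
    )


def write_gaze_table(rec: GazeRecording, path) -> None:
    """Write a recording as CSV; NaN gaze on invalid samples is preserved.

    Floats are written in shortest round-trip representation, so a
    read/write cycle is lossless and a second rewrite is byte-stable.
    """
    rec.to_frame().to_csv(path, index=False)


def read_sector_map(path) -> SectorMap:
    """Read a sector map table with columns label,start,end[,sector_index]."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("label", "start", "end"):
        if col not in df.columns:
            raise SchemaError(f"sector map missing column {col!r}")
    ivs = []
    for i, row in df.iterrows():
        idx = int(row["sector_index"]) if "sector_index" in df.columns else int(i)
        ivs.append((float(row["start"]), float(row["end"]), str(row["label"]), idx))
    return SectorMap(ivs)


def write_sector_map(smap: SectorMap, path) -> None:
    pd.DataFrame(
        [{"label": lab, "start": t0, "end": t1, "sector_index": idx}
         for t0, t1, lab, idx in smap.intervals]
    ).to_csv(path, index=False)


def read_head_pose(path) -> HeadPoseTrack:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "pitch", "roll", "yaw"):
        if col not in df.columns:
            raise SchemaError(f"head pose table missing column {col!r}")
    return HeadPoseTrack(df["t"].values, df["pitch"].values, df["roll"].values,
                         df["yaw"].values)


def write_head_pose(track: HeadPoseTrack, path) -> None:
    pd.DataFrame({"t": track.t, "pitch": track.pitch, "roll": track.roll,
                  "yaw": track.yaw}).to_csv(path, index=False)


def read_aoi_track(path) -> AoiTrack:
    """Read AOI observations: frame_t, x1,y1,...,x4,y4, confidence."""
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["frame_t"] + [f"{a}{i}" for i in range(1, 5) for a in ("x", "y")] + [
        "confidence"]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"AOI table missing column {col!r}")
    corners = np.stack(
        [df[[f"x{i}", f"y{i}"]].to_numpy(dtype=float) for i in range(1, 5)], axis=1
    )
    return AoiTrack(df["frame_t"].to_numpy(dtype=float), corners,
                    df["confidence"].to_numpy(dtype=float))


def write_aoi_track(track: AoiTrack, path) -> None:
    data = {"frame_t": track.frame_t}
    for i in range(4):
        data[f"x{i + 1}"] = track.corners[:, i, 0]
        data[f"y{i + 1}"] = track.corners[:, i, 1]
    data["confidence"] = track.confidence
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sector segmentation
# ---------------------------------------------------------------------------

def slice_by_sector(
    rec: GazeRecording, smap: SectorMap, label: str
) -> list[GazeRecording]:
    """Cut a recording into the segments carrying ``label``.

    One segment is returned per map interval with the requested label, in map
    order.  Samples falling inside exclusion windows are removed from the
    segments; intervals left empty are dropped.  An absent label yields an
    empty list.
    """
    segments: list[GazeRecording] = []
    excl = smap.exclusion_windows
    for t0, t1, lab, idx in smap.intervals:
        if lab != label:
            continue
        keep = (rec.t >= t0) & (rec.t < t1)
        for e0, e1 in excl:
            keep &= ~((rec.t >= e0) & (rec.t < e1))
        if not keep.any():
            continue
        segments.append(
            replace(
                rec,
                t=rec.t[keep], x=rec.x[keep], y=rec.y[keep],
                pupil=rec.pupil[keep], valid=rec.valid[keep],
                excluded=rec.excluded[keep],
            )
        )
    return segments
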