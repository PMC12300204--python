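"""Reading, writing and geometric conversion of jumping-point gaze recordings.

Recordings are monocular gaze streams sampled at a nominal 1000 Hz while the
participant follows a target dot that jumps between screen positions.  Gaze
and target coordinates are expressed in degrees of visual angle (DVA);
samples the tracker could not resolve (blinks, partial occlusions) carry NaN
gaze coordinates and a ``False`` validity flag.

The on-disk format is a plain CSV with one row per millisecond sample.  The
default column names follow the public GazeBase layout (``n`` timestamp,
``x``/``y`` gaze, ``val`` validity, ``xT``/``yT`` target) but can be remapped
for other trackers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Default CSV column mapping: logical field -> column name in the file.
DEFAULT_COLUMNS: dict[str, str] = {
    "timestamp": "n",
    "gaze_x": "x",
    "gaze_y": "y",
    "valid": "val",
    "target_x": "xT",
    "target_y": "yT",
}


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical monitor setup used to map pixels to degrees of visual angle.

    Parameters
    ----------
    viewing_distance
        Eye-to-screen distance in millimetres.
    resolution_x, resolution_y
        Screen resolution in pixels.
    width, height
        Physical screen size in millimetres.
    """

    viewing_distance: float = 550.0
    resolution_x: int = 1680
    resolution_y: int = 1050
    width: float = 474.0
    height: float = 297.0

    def __post_init__(self) -> None:
        for name in ("viewing_distance", "resolution_x", "resolution_y", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ScreenGeometry.{name} must be strictly positive")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered target positions of one jumping-point trial.

    Each position is shown for ``dwell_ms`` milliseconds; with the default
    100 positions at 1000 ms each a trial spans 100 s of recording.
    """

    positions: tuple[tuple[float, float], ...]
    dwell_ms: int = 1000

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValidationError("StimulusSchedule needs at least one position")
        if self.dwell_ms < 1:
            raise ValidationError("dwell_ms must be positive")

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def duration_ms(self) -> int:
        return self.count * self.dwell_ms

    def onset_sample(self, position_index: int) -> int:
        """First sample index of a position's dwell block (1 kHz sampling)."""
        if not 0 <= position_index < self.count:
            raise ValidationError(
                f"position_index {position_index} out of range [0, {self.count})"
            )
        return position_index * self.dwell_ms


@dataclass
class GazeRecording:
    """One session trial: per-sample gaze, target and validity arrays.

    Invariants (checked by :meth:`validate`): all arrays share one length,
    timestamps advance in strict 1 ms steps, and ``valid`` is ``False``
    exactly where either gaze coordinate is NaN.
    """

    timestamps: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        for name in ("gaze_x", "gaze_y", "target_x", "target_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.valid = np.asarray(self.valid, dtype=bool)
        self.validate()

    def __len__(self) -> int:
        return self.timestamps.size

    def validate(self) -> None:
        n = len(self)
        if n == 0:
            raise ValidationError("empty recording")
        arrays = (self.gaze_x, self.gaze_y, self.valid, self.target_x, self.target_y)
        if any(a.shape != (n,) for a in arrays):
            raise ValidationError("per-sample arrays must all have the same length")
        steps = np.diff(self.timestamps)
        if n > 1 and not np.allclose(steps, 1.0):
            raise ValidationError("timestamps must advance in strict 1 ms steps")
        nan_mask = np.isnan(self.gaze_x) | np.isnan(self.gaze_y)
        if not np.array_equal(self.valid, ~nan_mask):
            raise ValidationError("valid flags must be False exactly on NaN gaze samples")


def read_gaze_csv(
    path,
    columns: dict[str, str] | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> GazeRecording:
    """Read a gaze CSV into a :class:`GazeRecording`.

    Samples whose validity column is non-zero, or whose gaze coordinates are
    NaN, are marked invalid; their gaze coordinates are forced to NaN so the
    NaN mask and the validity flags agree.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    for logical, name in colmap.items():
        if name not in df.columns:
            raise FormatError(f"missing column {name!r} (maps to {logical!r})")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")

    ts = df[colmap["timestamp"]].to_numpy(dtype=np.float64)
    if ts.size > 1 and np.any(np.diff(ts) <= 0):
        raise ValidationError(f"{path}: timestamps are not strictly increasing")

    gx = df[colmap["gaze_x"]].to_numpy(dtype=np.float64)
    gy = df[colmap["gaze_y"]].to_numpy(dtype=np.float64)
    val = df[colmap["valid"]].to_numpy(dtype=np.float64)
    invalid = (val != 0) | np.isnan(gx) | np.isnan(gy)
    gx = np.where(invalid, np.nan, gx)
    gy = np.where(invalid, np.nan, gy)
    return GazeRecording(
        timestamps=ts,
        gaze_x=gx,
        gaze_y=gy,
        valid=~invalid,
        target_x=df[colmap["target_x"]].to_numpy(dtype=np.float64),
        target_y=df[colmap["target_y"]].to_numpy(dtype=np.float64),
        subject_id=subject_id,
        session_id=session_id,
    )


def write_gaze_csv(rec: GazeRecording, path, columns: dict[str, str] | None = None) -> None:
    """Write a recording as CSV; NaN is serialised as the literal ``NaN``."""
    rec.validate()
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.DataFrame(
        {
            colmap["timestamp"]: rec.timestamps,
            colmap["gaze_x"]: rec.gaze_x,
            colmap["gaze_y"]: rec.gaze_y,
            colmap["valid"]: (~rec.valid).astype(int),
            colmap["target_x"]: rec.target_x,
            colmap["target_y"]: rec.target_y,
        }
    )
    # 17 significant digits round-trips IEEE doubles exactly
    df.to_csv(path, index=False, na_rep="NaN", float_format="%.17g")


def pixels_to_dva(px: tuple[float, float], geom: ScreenGeometry) -> tuple[float, float]:
    """Convert a pixel coordinate pair into degrees of visual angle.

    The angle per axis is ``arctan(offset_mm / viewing_distance)`` with the
    offset measured from the screen centre, which stays exact at large
    eccentricities where the small-angle approximation drifts.
    """
    mm_per_px_x = geom.width / geom.resolution_x
    mm_per_px_y = geom.height / geom.resolution_y
    off_x = (px[0] - geom.resolution_x / 2.0) * mm_per_px_x
    off_y = (px[1] - geom.resolution_y / 2.0) * mm_per_px_y
    return (
        math.degrees(math.atan2(off_x, geom.viewing_distance)),
        math.degrees(math.atan2(off_y, geom.viewing_distance)),
    )


def dva_to_pixels(dva: tuple[float, float], geom: ScreenGeometry) -> tuple[float, float]:
    """Inverse of :func:`pixels_to_dva`."""
    off_x = math.tan(math.radians(dva[0])) * geom.viewing_distance
    off_y = math.tan(math.radians(dva[1])) * geom.viewing_distance
    return (
        off_x * geom.resolution_x / geom.width + geom.resolution_x / 2.0,
        off_y * geom.resolution_y / geom.height + geom.resolution_y / 2.0,
    )
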