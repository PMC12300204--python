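"""Event-aligned windowing of jumping-point recordings.

Each stimulus position contributes one 303-sample horizontal-position window
starting at stimulus onset, spanning the latency -> saccade -> fixation
sequence.  303 is the least window length whose three successive
point-to-point differences leave exactly 300 samples, i.e. three contiguous
100-sample segments on the common derivative support.

Positions whose dwell block contains any NaN gaze sample are dropped, and a
common position set is enforced across every trial of an experiment so all
subjects and sessions contribute the same stimulus indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io import GazeRecording, StimulusSchedule

#: Raw window length; three derivative passes leave WINDOW_LEN - 3 samples.
WINDOW_LEN = 303
#: Length of one analysis segment on the derivative support.
SEGMENT_LEN = 100
#: Number of segments kept per stimulus position.
N_SEGMENTS = 3


@dataclass(frozen=True)
class PositionWindow:
    """The 303 horizontal-position samples following one stimulus onset."""

    subject_id: str
    session_id: str
    position_index: int
    raw_x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw_x", np.asarray(self.raw_x, dtype=np.float64))
        if self.raw_x.shape != (WINDOW_LEN,):
            raise ValidationError(f"window must hold exactly {WINDOW_LEN} samples")
        if np.isnan(self.raw_x).any():
            raise ValidationError("window contains NaN samples")


@dataclass(frozen=True)
class SegmentBundle:
    """Three contiguous 100-sample index ranges over the derivative support."""

    window: PositionWindow
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise ValidationError(f"expected {N_SEGMENTS} segments")
        expect = 0
        for lo, hi in self.segments:
            if lo != expect or hi - lo != SEGMENT_LEN:
                raise ValidationError("segments must tile [0, 300) in 100-sample runs")
            expect = hi


def filter_valid_positions(rec: GazeRecording, schedule: StimulusSchedule) -> list[int]:
    """Indices of stimulus positions whose dwell block is NaN-free.

    A position is rejected as soon as any horizontal gaze sample within its
    full dwell block is NaN (blink or tracking loss anywhere near the event).
    """
    if len(rec) != schedule.duration_ms:
        raise ValidationError(
            f"recording length {len(rec)} != schedule duration {schedule.duration_ms}"
        )
    blocks = rec.gaze_x.reshape(schedule.count, schedule.dwell_ms)
    clean = ~np.isnan(blocks).any(axis=1)
    return np.flatnonzero(clean).tolist()


def select_common_positions(
    per_trial_valid: Mapping[object, Iterable[int]] | Sequence[Iterable[int]],
    x: int,
) -> list[int]:
    """First ``x`` stimulus indices valid in *every* trial, in stimulus order.

    Raises :class:`InsufficientDataError` (carrying the achievable count)
    when fewer than ``x`` positions survive in all trials simultaneously.
    """
    if x < 1:
        raise ValidationError("x must be >= 1")
    trials = (
        list(per_trial_valid.values())
        if isinstance(per_trial_valid, Mapping)
        else list(per_trial_valid)
    )
    if not trials:
        raise ValidationError("no trials given")
    common: set[int] = set(trials[0])
    for valid in trials[1:]:
        common &= set(valid)
    ordered = sorted(common)
    if len(ordered) < x:
        raise InsufficientDataError(
            f"only {len(ordered)} positions valid across all trials, need {x}",
            achievable=len(ordered),
        )
    return ordered[:x]


def extract_window(
    rec: GazeRecording, position_index: int, schedule: StimulusSchedule
) -> PositionWindow:
    """Cut the 303-sample horizontal window starting at a position's onset."""
    onset = schedule.onset_sample(position_index)
    if onset + WINDOW_LEN > len(rec):
        raise ValidationError("recording too short for window at this position")
    raw = rec.gaze_x[onset : onset + WINDOW_LEN]
    if np.isnan(raw).any():
        raise ValidationError(f"NaN inside window of position {position_index}")
    return PositionWindow(
        subject_id=rec.subject_id,
        session_id=rec.session_id,
        position_index=position_index,
        raw_x=raw,
    )


def split_segments(window: PositionWindow) -> SegmentBundle:
    """Partition the 300-sample derivative support into three 100-sample segments."""
    segs = tuple(
        (g * SEGMENT_LEN, (g + 1) * SEGMENT_LEN) for g in range(N_SEGMENTS)
    )
    return SegmentBundle(window=window, segments=segs)
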