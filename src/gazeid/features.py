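"""Dynamic and statistical eye-movement features per 100-sample segment.

From each 303-sample position window, seven 100-element channels are derived
per segment: point-to-point velocity, acceleration and jerk of the horizontal
gaze position, their point-to-point percentage changes, and the amplitude
spectrum of the segment's velocity (moduli of all 100 DFT coefficients).
The velocity/acceleration/jerk series (lengths 302/301/300) are aligned on
their trailing 300 samples so every channel covers the same raw support.

A 16-value statistical summary (min, max, mean, population std of velocity,
acceleration, jerk and the amplitude spectrum) condenses each segment for the
dense classifier.

All channels are min-max scaled to [0, 1]; scaling bounds are fitted on
training data only and applied with clipping elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .segmentation import SEGMENT_LEN, PositionWindow, SegmentBundle, split_segments

#: Channel order of the time-series feature matrix.
CHANNELS = ("v", "a", "j", "vc", "ac", "jc", "ft")
#: Channels summarised by the 16-value statistical vector.
STAT_CHANNELS = ("v", "a", "j", "ft")
#: Statistic order within each channel quadruple.
STAT_NAMES = ("min", "max", "mean", "std")

#: Sampling interval in seconds (1000 Hz).
DT = 1e-3
#: Denominators smaller than this yield 0 in percentage changes.
PCT_EPS = 1e-12


@dataclass(frozen=True)
class TimeSeriesFeatures:
    """One segment's 100 x 7 feature matrix (columns ordered as CHANNELS)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", arr)
        if arr.shape != (SEGMENT_LEN, len(CHANNELS)):
            raise ValidationError(f"expected shape {(SEGMENT_LEN, len(CHANNELS))}")

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


@dataclass(frozen=True)
class StatFeatures:
    """(min, max, mean, std) of v, a, j, Ft — a fixed-order 16-vector."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", arr)
        if arr.shape != (len(STAT_CHANNELS) * len(STAT_NAMES),):
            raise ValidationError("expected a 16-value vector")


@dataclass(frozen=True)
class LabeledSample:
    """A feature vector with its identity label and provenance."""

    features: TimeSeriesFeatures | StatFeatures
    label: int
    session_id: str
    position_index: int
    segment_index: int


def derivative(x: np.ndarray, dt: float = DT) -> np.ndarray:
    """Point-to-point first derivative ``(x[i+1] - x[i]) / dt`` (length - 1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValidationError("need at least 2 samples to differentiate")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    return np.diff(x) / dt


def pct_change(s: np.ndarray, eps: float = PCT_EPS) -> np.ndarray:
    """Point-to-point fractional change ``(s[i+1] - s[i]) / s[i]``.

    Near-zero denominators (|s[i]| < eps) yield 0 — fixation velocity sits
    at ~0 for most of a segment, so unguarded division would blow up.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.size < 2:
        raise ValidationError("need at least 2 samples")
    den = s[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.diff(s) / den
    return np.where(np.abs(den) < eps, 0.0, out)


def amplitude_spectrum(seg: np.ndarray) -> np.ndarray:
    """Moduli of all n DFT coefficients, |sum_m a_m exp(-2*pi*i*m*k/n)|."""
    seg = np.asarray(seg, dtype=np.float64)
    if seg.shape != (SEGMENT_LEN,):
        raise ValidationError(f"amplitude spectrum expects {SEGMENT_LEN} samples")
    return np.abs(np.fft.fft(seg))


def minmax_scale(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Scale into [0, 1] with clipping; a degenerate range maps to zeros."""
    s = np.asarray(s, dtype=np.float64)
    if hi < lo:
        raise ValidationError("hi must be >= lo")
    if hi == lo:
        return np.zeros_like(s)
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)


def raw_segment_channels(window: PositionWindow, bundle: SegmentBundle | None = None) -> np.ndarray:
    """Unscaled (3, 100, 7) channel stack for one position window.

    Velocity, acceleration and jerk are differentiated over the full window
    (lengths 302/301/300), truncated to their trailing 300 samples, and
    sliced per segment; percentage changes are computed within each segment
    and right-padded (repeating the last value) back to 100 elements; the
    spectrum channel is the DFT modulus of the segment's unscaled velocity.
    """
    bundle = bundle or split_segments(window)
    v = derivative(window.raw_x)
    a = derivative(v)
    j = derivative(a)
    support = j.size  # 300-sample common support, trailing-aligned
    v, a = v[-support:], a[-support:]

    out = np.empty((len(bundle.segments), SEGMENT_LEN, len(CHANNELS)))
    for g, (lo, hi) in enumerate(bundle.segments):
        vs, as_, js = v[lo:hi], a[lo:hi], j[lo:hi]
        out[g, :, 0] = vs
        out[g, :, 1] = as_
        out[g, :, 2] = js
        for col, series in ((3, vs), (4, as_), (5, js)):
            pc = pct_change(series)
            out[g, :, col] = np.concatenate([pc, pc[-1:]])
        out[g, :, 6] = amplitude_spectrum(vs)
    return out


def build_ts_features(
    window: PositionWindow,
    bundle: SegmentBundle | None = None,
    scalers: np.ndarray | None = None,
) -> list[TimeSeriesFeatures]:
    """The three per-segment 100 x 7 feature matrices of one window.

    ``scalers`` is a (7, 2) array of per-channel (lo, hi) bounds, normally
    fitted on the training split; ``None`` returns unscaled channels.
    """
    raw = raw_segment_channels(window, bundle)
    if scalers is not None:
        raw = scale_channels(raw, scalers)
    return [TimeSeriesFeatures(raw[g]) for g in range(raw.shape[0])]


def build_stat_features(ts: TimeSeriesFeatures) -> StatFeatures:
    """16-value summary: (min, max, mean, population std) of v, a, j, Ft."""
    vals = []
    for name in STAT_CHANNELS:
        ch = ts.channel(name)
        vals.extend((ch.min(), ch.max(), ch.mean(), ch.std()))
    return StatFeatures(np.asarray(vals))


def fit_channel_scalers(raw: np.ndarray) -> np.ndarray:
    """Per-channel (lo, hi) over a stack of raw channel matrices.

    ``raw`` has shape (..., 100, 7); bounds are taken over all leading axes
    and time steps, one pair per channel.
    """
    flat = np.asarray(raw, dtype=np.float64).reshape(-1, len(CHANNELS))
    return np.stack([flat.min(axis=0), flat.max(axis=0)], axis=1)


def scale_channels(raw: np.ndarray, scalers: np.ndarray) -> np.ndarray:
    """Apply per-channel min-max bounds (with clipping) to a channel stack."""
    scalers = np.asarray(scalers, dtype=np.float64)
    if scalers.shape != (len(CHANNELS), 2):
        raise ValidationError("scalers must have shape (7, 2)")
    lo = scalers[:, 0]
    span = scalers[:, 1] - lo
    safe = np.where(span > 0, span, 1.0)
    out = np.clip((raw - lo) / safe, 0.0, 1.0)
    return np.where(span > 0, out, 0.0)
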