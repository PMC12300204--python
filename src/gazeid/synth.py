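"""Synthetic jumping-point gaze generator with per-subject oculomotor signatures.

The simulator reproduces the event structure of a jumping-point trial: after
each stimulus jump the eye holds the previous fixation for a saccadic latency
(normally ~150-200 ms), executes a rapid saccade whose peak velocity follows
the main sequence (a saturating, monotone function of amplitude, 300-500 deg/s
for 4-20 deg jumps), and then fixates on the new target with slow drift and
white micro-movement noise.  Blinks are injected afterwards as NaN runs.

A subject's identity lives in the parameters of this process
(:class:`SubjectProfile`); session-to-session template aging is modelled as
bounded multiplicative/additive perturbations (:class:`SessionEffect`).

Saccade trajectories use the minimum-jerk profile, the standard closed-form
approximation to saccadic kinematics: position along the jump follows
``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`` with peak velocity
``1.875 * amplitude / duration``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import GazeRecording, StimulusSchedule

#: Amplitude constant (DVA) of the saturating main sequence
#: v_peak(A) = vpeak_scale * (1 - exp(-A / MAIN_SEQUENCE_A0)).
MAIN_SEQUENCE_A0 = 5.0

#: Horizontal/vertical stimulus bounds in DVA (within the GazeBase screen).
SCREEN_BOUNDS = (18.0, 10.0)

_SAMPLE_RATE_HZ = 1000


@dataclass(frozen=True)
class SubjectProfile:
    """Oculomotor parameter set defining one simulated person.

    Parameters
    ----------
    latency_mean, latency_sd
        Saccadic latency distribution in ms (population range 150-200 ms).
    vpeak_scale
        Saturation peak velocity of the main sequence, deg/s; with the
        default the 4-20 deg jumps of the task peak at roughly 290-510 deg/s.
    duration_slope
        Extra saccade duration per degree of amplitude (ms/deg) added on top
        of the duration implied by the main sequence; 0 keeps the pure
        minimum-jerk relation ``duration = 1.875 * A / v_peak``.
    fixation_noise_sd
        White micro-movement noise during fixation, DVA.
    drift_rate
        Slow fixation drift speed, DVA/s (random direction per fixation).
    undershoot_frac
        Fraction of the jump the primary saccade falls short by, in [0, 0.2].
    blink_rate
        Expected blink events per stimulus position (Poisson).
    """

    latency_mean: float = 170.0
    latency_sd: float = 15.0
    vpeak_scale: float = 520.0
    duration_slope: float = 0.0
    fixation_noise_sd: float = 0.05
    drift_rate: float = 0.3
    undershoot_frac: float = 0.05
    blink_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 100.0 <= self.latency_mean <= 300.0:
            raise ValidationError("latency_mean must lie within [100, 300] ms")
        if not 0.0 <= self.undershoot_frac <= 0.2:
            raise ValidationError("undershoot_frac must lie within [0, 0.2]")
        if self.vpeak_scale <= 0 or self.latency_sd < 0 or self.fixation_noise_sd < 0:
            raise ValidationError("scale/sd parameters must be non-negative")
        if self.blink_rate < 0:
            raise ValidationError("blink_rate must be non-negative")

    def peak_velocity(self, amplitude: float) -> float:
        """Main-sequence peak velocity (deg/s) for a saccade of given amplitude."""
        return self.vpeak_scale * (1.0 - math.exp(-amplitude / MAIN_SEQUENCE_A0))


@dataclass(frozen=True)
class SessionEffect:
    """Bounded session-level perturbation emulating template aging."""

    gain_drift: float = 1.0
    latency_shift: float = 0.0
    noise_inflation: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_drift <= 0 or abs(math.log(self.gain_drift)) > 0.2:
            raise ValidationError("gain_drift must satisfy |log(gain)| <= 0.2")
        if abs(self.latency_shift) > 50:
            raise ValidationError("latency_shift bounded to +/-50 ms")
        if not 0.5 <= self.noise_inflation <= 2.0:
            raise ValidationError("noise_inflation bounded to [0.5, 2]")

    @staticmethod
    def sample(rng: np.random.Generator, scale: float = 0.05) -> "SessionEffect":
        """Draw a mild random session perturbation (log-gain sd = ``scale``)."""
        return SessionEffect(
            gain_drift=float(np.exp(np.clip(rng.normal(0.0, scale), -0.2, 0.2))),
            latency_shift=float(np.clip(rng.normal(0.0, 5.0), -50, 50)),
            noise_inflation=float(np.clip(rng.lognormal(0.0, scale), 0.5, 2.0)),
        )


def generate_schedule(
    count: int = 100,
    dwell_ms: int = 1000,
    amplitude_range: tuple[float, float] = (4.0, 20.0),
    seed: int = 0,
) -> StimulusSchedule:
    """Random jumping-point schedule with jump amplitudes in ``amplitude_range``.

    Consecutive positions are separated by a jump whose Euclidean amplitude is
    drawn uniformly from the range; directions are re-drawn until the target
    stays within the screen bounds.
    """
    if count < 1:
        raise ValidationError("count must be >= 1")
    lo, hi = amplitude_range
    if not (0 < lo <= hi):
        raise ValidationError(f"empty amplitude range {amplitude_range}")
    bx, by = SCREEN_BOUNDS
    if lo > 2 * min(bx, by):
        raise ValidationError("amplitudes exceed screen bounds")
    rng = np.random.default_rng(seed)
    pos = np.array([rng.uniform(-5, 5), rng.uniform(-3, 3)])
    positions = [tuple(pos)]
    for _ in range(count - 1):
        for attempt in range(200):
            amp = rng.uniform(lo, hi)
            ang = rng.uniform(0, 2 * np.pi)
            cand = pos + amp * np.array([np.cos(ang), np.sin(ang)])
            if abs(cand[0]) <= bx and abs(cand[1]) <= by:
                break
        else:  # horizontal move toward centre always fits (bounds span >= 2*hi)
            cand = pos + np.array([-np.sign(pos[0]) * amp, 0.0])
        pos = cand
        positions.append((float(pos[0]), float(pos[1])))
    return StimulusSchedule(positions=tuple(positions), dwell_ms=dwell_ms)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trial(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    effect: SessionEffect | None = None,
    seed: int = 0,
    subject_id: str = "",
    session_id: str = "",
) -> GazeRecording:
    """Simulate one jumping-point trial for a subject at 1000 Hz.

    Deterministic given ``seed``: the per-sample gaze track is a pure
    function of the profile, schedule, session effect and seed.
    """
    effect = effect or SessionEffect()
    rng = np.random.default_rng(seed)
    n = schedule.duration_ms
    gaze = np.empty((n, 2))
    targets = np.asarray(schedule.positions, dtype=float)
    target_track = np.repeat(targets, schedule.dwell_ms, axis=0)

    vpeak_gain = effect.gain_drift
    sigma = profile.fixation_noise_sd * effect.noise_inflation

    # fixation state: anchor position, global start sample, drift velocity
    anchor = np.array([0.0, 0.0])
    fix_start = 0
    drift_vec = np.zeros(2)

    def fixate(start: int, stop: int, out: np.ndarray) -> None:
        t = (np.arange(start, stop) - fix_start) / _SAMPLE_RATE_HZ
        out[start:stop] = anchor + t[:, None] * drift_vec

    for k in range(schedule.count):
        onset = schedule.onset_sample(k)
        block_end = onset + schedule.dwell_ms
        target = targets[k]

        latency = profile.latency_mean + effect.latency_shift
        if profile.latency_sd > 0:
            latency = rng.normal(latency, profile.latency_sd)
        latency = int(round(np.clip(latency, 80, 400)))

        sacc_start = min(onset + latency, block_end)
        fixate(onset, sacc_start, gaze)

        eye = anchor + drift_vec * (sacc_start - fix_start) / _SAMPLE_RATE_HZ
        landing = target - profile.undershoot_frac * (target - eye)
        jump = landing - eye
        amp = float(np.hypot(*jump))
        if amp < 1e-9:
            continue  # stimulus did not move appreciably; keep fixating

        vpeak = vpeak_gain * profile.peak_velocity(amp)
        dur_ms = 1875.0 * amp / vpeak + profile.duration_slope * amp
        dur = max(int(round(dur_ms)), 2)
        sacc_end = min(sacc_start + dur, block_end)
        tau = (np.arange(sacc_start, sacc_end) - sacc_start + 1.0) / dur_ms
        gaze[sacc_start:sacc_end] = eye + np.clip(_min_jerk(np.minimum(tau, 1.0)), 0, 1)[:, None] * jump

        anchor = landing
        fix_start = sacc_end
        if profile.drift_rate > 0:
            theta = rng.uniform(0, 2 * np.pi)
            drift_vec = profile.drift_rate * np.array([np.cos(theta), np.sin(theta)])
        else:
            drift_vec = np.zeros(2)
        fixate(sacc_end, block_end, gaze)

    if sigma > 0:
        gaze += rng.normal(0.0, sigma, size=gaze.shape)

    rec = GazeRecording(
        timestamps=np.arange(n, dtype=float),
        gaze_x=gaze[:, 0],
        gaze_y=gaze[:, 1],
        valid=np.ones(n, dtype=bool),
        target_x=target_track[:, 0],
        target_y=target_track[:, 1],
        subject_id=subject_id,
        session_id=session_id,
    )
    if profile.blink_rate > 0:
        rec = inject_missing(
            rec,
            blink_rate=profile.blink_rate,
            seed=int(rng.integers(2**31)),
            dwell_ms=schedule.dwell_ms,
        )
    return rec


def inject_missing(
    rec: GazeRecording,
    blink_rate: float,
    blink_len_ms: tuple[int, int] = (50, 150),
    seed: int = 0,
    dwell_ms: int = 1000,
) -> GazeRecording:
    """Replace Poisson-distributed blink events with NaN runs, per position.

    ``blink_rate`` is the expected number of blinks per stimulus position;
    each blink blanks a uniformly-drawn run of ``blink_len_ms`` milliseconds,
    clipped to the position's dwell block.  ``rate == 0`` returns the
    recording unchanged.
    """
    if blink_rate < 0:
        raise ValidationError("blink_rate must be non-negative")
    if blink_rate == 0:
        return rec
    rng = np.random.default_rng(seed)
    gx = rec.gaze_x.copy()
    gy = rec.gaze_y.copy()
    n = len(rec)
    for start in range(0, n, dwell_ms):
        stop = min(start + dwell_ms, n)
        for _ in range(rng.poisson(blink_rate)):
            length = int(rng.integers(blink_len_ms[0], blink_len_ms[1] + 1))
            b0 = int(rng.integers(start, stop))
            b1 = min(b0 + length, stop)
            gx[b0:b1] = np.nan
            gy[b0:b1] = np.nan
    nan_mask = np.isnan(gx) | np.isnan(gy)
    return GazeRecording(
        timestamps=rec.timestamps,
        gaze_x=gx,
        gaze_y=gy,
        valid=~nan_mask,
        target_x=rec.target_x,
        target_y=rec.target_y,
        subject_id=rec.subject_id,
        session_id=rec.session_id,
    )


def make_cohort(
    n_subjects: int,
    seed: int = 0,
    vpeak_base: float = 300.0,
    vpeak_ratio: float = 1.25,
) -> list[SubjectProfile]:
    """Well-separated subject profiles for identification experiments.

    Peak-velocity scales are spaced geometrically by ``vpeak_ratio`` (adjacent
    subjects differ by >= 25% with the default), and latency means are spread
    over the physiological 150-200 ms band.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for k in range(n_subjects):
        profiles.append(
            SubjectProfile(
                latency_mean=150.0 + 50.0 * k / max(n_subjects - 1, 1),
                latency_sd=10.0,
                vpeak_scale=vpeak_base * vpeak_ratio**k,
                fixation_noise_sd=0.05,
                drift_rate=0.2 + 0.05 * float(rng.uniform()),
                undershoot_frac=0.02 + 0.1 * k / max(n_subjects, 1),
                seed=int(rng.integers(2**31)),
            )
        )
    return profiles


def simulate_dataset(
    profiles: list[SubjectProfile],
    n_sessions: int,
    schedule: StimulusSchedule,
    seed: int = 0,
    session_effect_scale: float = 0.05,
) -> dict[tuple[str, str], GazeRecording]:
    """Simulate one trial per subject per session on a common schedule.

    Returns a mapping ``(subject_id, session_id) -> GazeRecording``.  Session
    effects are drawn once per (subject, session) pair, so templates age
    independently per person.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], GazeRecording] = {}
    for i, prof in enumerate(profiles):
        sid = f"S{i:02d}"
        for s in range(n_sessions):
            eff = SessionEffect.sample(rng, scale=session_effect_scale) if s else SessionEffect()
            out[(sid, f"R{s:02d}")] = simulate_trial(
                prof,
                schedule,
                effect=eff,
                seed=int(rng.integers(2**31)),
                subject_id=sid,
                session_id=f"R{s:02d}",
            )
    return out
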