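"""Saccade detection, selection and exclusion rules.

Velocity is estimated with a 4 ms sliding window; segments faster than
3000 deg/s or overlapping lost tracking are treated as missing.  The
primary saccade of a trial is the first movement after target onset
exceeding 1° amplitude.  Trials are excluded when peak velocity falls
outside 80–2500 deg/s or the target is reached before 180 ms or after
580 ms; participants are excluded when any condition retains fewer than
10 valid trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import TrialEvent
from .gaze_io import GazeRecording

__all__ = [
    "DetectionThresholds",
    "SaccadeRecord",
    "sliding_velocity",
    "detect_primary_saccade",
    "detect_session",
    "apply_exclusions",
    "apply_participant_exclusion",
    "saccade_table",
]


@dataclass
class DetectionThresholds:
    """Tunable constants of detection and exclusion."""

    onset_threshold: float = 30.0  # deg/s speed criterion for saccade bounds
    refine_floor: float = 5.0  # deg/s; crossings walk back/forward to this
    refine_limit: float = 20.0  # ms maximal boundary refinement
    min_duration: float = 10.0  # ms minimal supra-threshold run
    min_amplitude: float = 1.0  # degrees, primary-saccade selection
    velocity_window: float = 4.0  # ms sliding window
    max_speed: float = 3000.0  # deg/s, faster segments treated as missing
    peak_velocity_bounds: tuple[float, float] = (80.0, 2500.0)  # deg/s
    response_time_bounds: tuple[float, float] = (180.0, 580.0)  # ms
    response_window: float = 1000.0  # ms scanned after target onset
    # "offset": response time = saccade offset − target onset (default);
    # "radius": first post-onset sample within arrival_radius of the target.
    response_time_mode: str = "offset"
    arrival_radius: float = 2.0  # degrees, used by the "radius" mode
    min_valid_trials: int = 10  # per condition, participant exclusion


@dataclass
class SaccadeRecord:
    """One detected primary saccade and its scalar measures.

    Positions are side-mirrored after detection (``x → −x`` for left
    targets) so all analyses treat rightward-positive coordinates.
    """

    trial_index: int
    condition: str
    target_side: str
    onset: float  # ms, absolute
    offset: float  # ms, absolute
    latency: float  # ms, onset − target_onset (saccadic RT)
    response_time: float  # ms, arrival − target_onset
    amplitude: float  # degrees, straight-line start → end
    peak_velocity: float  # deg/s within [onset, offset]
    endpoint: tuple[float, float]  # degrees, mirrored
    trajectory: np.ndarray = field(repr=False)  # (n, 2) mirrored positions, 1/ms
    valid: bool = True
    rejection_reason: Optional[str] = None


def sliding_velocity(
    positions: np.ndarray,
    window: float = 4.0,
    dt: float = 1.0,
    max_speed: float = 3000.0,
) -> np.ndarray:
    """Instantaneous speed (deg/s) from a centred sliding window.

    ``positions`` is an (n, 2) array of x/y in degrees sampled every
    ``dt`` ms.  The speed at sample *t* is the Euclidean displacement
    across the centred ``window`` divided by the window length.  Samples
    whose window overlaps missing data, and segments faster than
    ``max_speed``, are returned as NaN.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = np.column_stack((pos, np.zeros_like(pos)))
    half = int(round(window / dt / 2))
    n = len(pos)
    if n < 2 * half + 1:
        raise ValueError(f"need at least {2 * half + 1} samples for a {window} ms window")
    speed = np.full(n, np.nan)
    disp = pos[2 * half :] - pos[: n - 2 * half]
    speed[half : n - half] = np.hypot(disp[:, 0], disp[:, 1]) / (2 * half * dt) * 1000.0
    # windows touching missing samples are missing
    bad = ~np.isfinite(pos).all(axis=1)
    if bad.any():
        k = np.convolve(bad.astype(int), np.ones(2 * half + 1, dtype=int), mode="same")
        speed[k > 0] = np.nan
    speed[speed > max_speed] = np.nan
    return speed


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_primary_saccade(
    recording: GazeRecording,
    trial: TrialEvent,
    thresholds: DetectionThresholds | None = None,
) -> Optional[SaccadeRecord]:
    """First saccade after target onset with amplitude > 1°, or ``None``.

    Candidate saccades are maximal runs of speed above the onset
    threshold lasting at least ``min_duration`` ms.  Onset and offset are
    the threshold crossings; peak velocity is the maximum sliding-window
    speed inside them; amplitude is the straight-line start→end distance.
    """
    th = thresholds or DetectionThresholds()
    dt = recording.dt
    i0 = recording.index_at(trial.target_onset)
    i1 = min(len(recording.t), recording.index_at(trial.target_onset + th.response_window) + 1)
    pad = int(round(th.velocity_window / dt))  # margin so edge windows are defined
    lo = max(0, i0 - pad)
    pos = np.column_stack((recording.x[lo:i1], recording.y[lo:i1]))
    pos[~recording.valid[lo:i1]] = np.nan
    speed = sliding_velocity(pos, th.velocity_window, dt, th.max_speed)

    min_run = int(round(th.min_duration / dt))
    mask = np.zeros(len(speed), dtype=bool)
    finite = np.isfinite(speed)
    mask[finite] = speed[finite] > th.onset_threshold
    refine = int(round(th.refine_limit / dt))
    for start, stop in _supra_runs(mask):
        if stop - start < min_run:
            continue
        if lo + start < i0:  # movement already in flight at target onset
            continue
        # refine boundaries: walk the threshold crossings back/forward to
        # where speed falls to the fixational floor, so onset/offset track
        # the true movement rather than the 30 deg/s crossing
        s0 = start
        while (
            start > max(i0 - lo, s0 - refine)
            and np.isfinite(speed[start - 1])
            and speed[start - 1] > th.refine_floor
            and speed[start - 1] <= speed[start]
        ):
            start -= 1
        e0 = stop
        while (
            stop < min(len(speed), e0 + refine)
            and np.isfinite(speed[stop])
            and speed[stop] > th.refine_floor
            and speed[stop] <= speed[stop - 1]
        ):
            stop += 1
        traj = pos[start:stop]
        if not np.isfinite(traj).all():
            continue
        amp = float(np.hypot(*(traj[-1] - traj[0])))
        if amp <= th.min_amplitude:
            continue
        onset_t = float(recording.t[lo + start])
        offset_t = float(recording.t[lo + stop - 1])
        if th.response_time_mode == "radius":
            target_x = (-1.0 if trial.target_side == "left" else 1.0) * 9.3
            inside = np.hypot(pos[start:, 0] - target_x, pos[start:, 1]) <= th.arrival_radius
            arrival_idx = np.flatnonzero(inside)
            arrival_t = (
                float(recording.t[lo + start + arrival_idx[0]]) if len(arrival_idx) else offset_t
            )
        else:
            arrival_t = offset_t
        mirror = -1.0 if trial.target_side == "left" else 1.0
        mtraj = traj.copy()
        mtraj[:, 0] *= mirror
        return SaccadeRecord(
            trial_index=trial.trial_index,
            condition=trial.condition,
            target_side=trial.target_side,
            onset=onset_t,
            offset=offset_t,
            latency=onset_t - trial.target_onset,
            response_time=arrival_t - trial.target_onset,
            amplitude=amp,
            peak_velocity=float(np.nanmax(speed[start:stop])),
            endpoint=(float(mtraj[-1, 0]), float(mtraj[-1, 1])),
            trajectory=mtraj,
        )
    return None


def apply_exclusions(
    saccade: SaccadeRecord,
    trial: TrialEvent | None = None,
    thresholds: DetectionThresholds | None = None,
) -> SaccadeRecord:
    """Flag a saccade invalid under the velocity and response-time bounds."""
    th = thresholds or DetectionThresholds()
    vmin, vmax = th.peak_velocity_bounds
    tmin, tmax = th.response_time_bounds
    reason = None
    if saccade.peak_velocity < vmin or saccade.peak_velocity > vmax:
        reason = f"peak velocity {saccade.peak_velocity:.1f} outside [{vmin:g}, {vmax:g}] deg/s"
    elif saccade.response_time < tmin:
        reason = f"target reached before {tmin:g} ms"
    elif saccade.response_time > tmax:
        reason = f"target reached after {tmax:g} ms"
    saccade.valid = reason is None
    saccade.rejection_reason = reason
    return saccade


def detect_session(
    recording: GazeRecording, thresholds: DetectionThresholds | None = None
) -> list[SaccadeRecord]:
    """Detect, select and flag the primary saccade of every trial."""
    th = thresholds or DetectionThresholds()
    out = []
    for trial in recording.events:
        rec = detect_primary_saccade(recording, trial, th)
        if rec is not None:
            out.append(apply_exclusions(rec, trial, th))
    return out


def apply_participant_exclusion(
    counts: Mapping[str, Mapping[str, int]] | Mapping[str, int],
    min_trials: int = 10,
) -> bool:
    """Keep/drop decision from per-condition valid-trial counts.

    ``counts`` is either ``{condition: n}`` for a single session or
    ``{session: {condition: n}}``; the participant is dropped entirely if
    any condition in any session has fewer than ``min_trials`` valid
    trials.  Returns True to keep.
    """
    values: Iterable[int]
    first = next(iter(counts.values()))
    if isinstance(first, Mapping):
        values = [v for sess in counts.values() for v in sess.values()]
    else:
        values = list(counts.values())
    return all(v >= min_trials for v in values)


def saccade_table(saccades: Iterable[SaccadeRecord]) -> pd.DataFrame:
    """Per-trial scalar table of detected saccades."""
    rows = [
        {
            "trial_index": s.trial_index,
            "condition": s.condition,
            "target_side": s.target_side,
            "onset_ms": s.onset,
            "offset_ms": s.offset,
            "latency_ms": s.latency,
            "response_time_ms": s.response_time,
            "amplitude_deg": s.amplitude,
            "peak_velocity": s.peak_velocity,
            "endpoint_x": s.endpoint[0],
            "endpoint_y": s.endpoint[1],
            "valid": s.valid,
            "rejection_reason": s.rejection_reason or "",
        }
        for s in saccades
    ]
    return pd.DataFrame(rows)
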