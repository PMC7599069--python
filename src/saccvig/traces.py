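"""Time-normalized within-saccade kinematics and position autocorrelation.

Saccades of different durations are compared by linearly interpolating
50 points along each movement (0–100% of its duration).  Instantaneous
velocity is the finite difference of the normalized positions rescaled
by the true duration and smoothed over 3 time-points; acceleration
differentiates the velocity trace and smooths over 5.

Across trials, the position at each normalized time-point can be
correlated with the position at every other, giving a 50×50 time×time
autocorrelation matrix (Fisher-transformed).  Rising correlations index
accumulating signal-dependent noise; reduced late-saccade correlations
index corrective negative feedback during the movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NormalizedTrace",
    "AutocorrMatrix",
    "time_normalize",
    "profile_velocity",
    "profile_acceleration",
    "kinematic_profiles",
    "autocorrelation_matrix",
    "covariance_matrix",
    "FISHER_Z_CAP",
]

N_POINTS = 50
#: display cap for Fisher z of |r| → 1 (the diagonal); inference excludes it
FISHER_Z_CAP = float(np.arctanh(0.9999))


@dataclass
class NormalizedTrace:
    """50 points along a saccade on the 0–100% duration axis."""

    values: np.ndarray
    kind: str  # "position" | "velocity" | "acceleration"
    duration_ms: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POINTS,):
            raise ValueError(f"a normalized trace has exactly {N_POINTS} points")

    @property
    def time_axis(self) -> np.ndarray:
        """Percent of saccade duration, 0 → 100."""
        return np.linspace(0.0, 100.0, N_POINTS)


@dataclass
class AutocorrMatrix:
    """Across-trial time×time correlation of within-saccade position."""

    z: np.ndarray = field(repr=False)  # 50×50 Fisher-transformed r
    r: np.ndarray = field(repr=False)  # raw correlations
    n_trials: int = 0
    participant_id: str = ""
    condition: str = ""


def time_normalize(trajectory: np.ndarray, n_points: int = N_POINTS,
                   dt: float = 1.0) -> NormalizedTrace:
    """Linearly interpolate ``n_points`` equally spaced points over a saccade.

    ``trajectory`` is the per-ms horizontal position from onset to
    offset; the endpoints are preserved exactly.
    """
    x = np.asarray(trajectory, dtype=float)
    if x.ndim == 2:
        x = x[:, 0]
    if len(x) < 2:
        raise ValueError("need at least two samples to normalize")
    duration = (len(x) - 1) * dt
    src = np.arange(len(x)) * dt
    dst = np.linspace(0.0, duration, n_points)
    return NormalizedTrace(np.interp(dst, src, x), "position", duration)


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with window truncation at the edges."""
    if width <= 1:
        return values.copy()
    half = width // 2
    out = np.empty_like(values)
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def profile_velocity(trace: NormalizedTrace, smooth: int = 3) -> NormalizedTrace:
    """Instantaneous velocity (deg/s) along the normalized time axis."""
    if trace.kind != "position":
        raise ValueError("velocity is derived from a position trace")
    dt_ms = trace.duration_ms / (N_POINTS - 1)
    v = np.gradient(trace.values, dt_ms) * 1000.0
    return NormalizedTrace(_smooth(v, smooth), "velocity", trace.duration_ms)


def profile_acceleration(trace: NormalizedTrace, smooth: int = 5) -> NormalizedTrace:
    """Instantaneous acceleration (deg/s²) from a velocity trace."""
    if trace.kind != "velocity":
        raise ValueError("acceleration is derived from a velocity trace")
    dt_ms = trace.duration_ms / (N_POINTS - 1)
    a = np.gradient(trace.values, dt_ms) * 1000.0
    return NormalizedTrace(_smooth(a, smooth), "acceleration", trace.duration_ms)


def kinematic_profiles(
    trajectory: np.ndarray,
    mode: str = "normalized_first",
    dt: float = 1.0,
) -> tuple[NormalizedTrace, NormalizedTrace, NormalizedTrace]:
    """Position, velocity and acceleration traces for one saccade.

    ``mode="normalized_first"`` (default) interpolates position to 50
    points and differentiates on the normalized grid.  ``"raw_first"``
    differentiates the raw per-ms trace and interpolates the resulting
    velocity/acceleration afterwards; the two give very similar results
    on smooth saccades.
    """
    pos = time_normalize(trajectory, dt=dt)
    if mode == "normalized_first":
        vel = profile_velocity(pos)
        acc = profile_acceleration(vel)
        return pos, vel, acc
    if mode != "raw_first":
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(trajectory, dtype=float)
    if x.ndim == 2:
        x = x[:, 0]
    v_raw = np.gradient(x, dt) * 1000.0
    a_raw = np.gradient(v_raw, dt) * 1000.0
    vel = NormalizedTrace(
        _smooth(time_normalize(v_raw, dt=dt).values, 3), "velocity", pos.duration_ms
    )
    acc = NormalizedTrace(
        _smooth(time_normalize(a_raw, dt=dt).values, 5), "acceleration", pos.duration_ms
    )
    return pos, vel, acc


def _stack(traces: Sequence[NormalizedTrace] | np.ndarray) -> np.ndarray:
    if isinstance(traces, np.ndarray):
        arr = traces.astype(float)
    else:
        arr = np.vstack([t.values for t in traces])
    if arr.ndim != 2 or arr.shape[1] != N_POINTS:
        raise ValueError(f"expected an (n_trials, {N_POINTS}) stack of traces")
    return arr


def autocorrelation_matrix(
    traces: Sequence[NormalizedTrace] | np.ndarray,
    participant_id: str = "",
    condition: str = "",
) -> AutocorrMatrix:
    """Time×time Pearson correlation of position across trials, Fisher z.

    Entry (i, j) correlates, across trials, the (side-mirrored)
    horizontal position at normalized time i with that at time j.  The
    Fisher transform ``z = atanh(r)`` is applied with |r| capped at
    0.9999 so the unit diagonal stays finite for display; inference
    should exclude the diagonal.  Time-points with zero variance across
    trials yield NaN rows/columns.
    """
    arr = _stack(traces)
    if len(arr) < 3:
        raise ValueError("need at least three trials for an autocorrelation matrix")
    sd = arr.std(axis=0)
    degenerate = sd <= 1e-10 * (np.abs(arr).max(axis=0) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    z = np.arctanh(np.clip(r, -0.9999, 0.9999))
    return AutocorrMatrix(z=z, r=r, n_trials=len(arr),
                          participant_id=participant_id, condition=condition)


def covariance_matrix(traces: Sequence[NormalizedTrace] | np.ndarray) -> np.ndarray:
    """Across-trial time×time covariance of position (deg²)."""
    arr = _stack(traces)
    if len(arr) < 3:
        raise ValueError("need at least three trials for a covariance matrix")
    return np.cov(arr, rowvar=False)
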