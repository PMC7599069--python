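"""Fixation-period analysis: cleaning, microsaccades, drift and tremor.

The 1400 ms between cue and the earliest possible target is scanned
for fixational eye movements.  Trials containing a saccade (≥ 1°) or a
blink are dropped; within surviving trials, samples deviating more than
1.8° from fixation or moving faster than 30 deg/s are removed, and the
remaining contiguous segments are analysed for microsaccade counts
(< 1°, median-based velocity-threshold detection), median drift speed
(microsaccades excised) and the amplitude spectrum of horizontal
position in early (200–700 ms) and late (700–1200 ms) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as ssig

from .saccades import sliding_velocity

__all__ = [
    "FixationWindow",
    "Microsaccade",
    "clean_fixation",
    "detect_microsaccades",
    "drift_speed",
    "fixation_spectrum",
    "SPECTRUM_WINDOWS",
]

SPECTRUM_WINDOWS = {"early": (200, 700), "late": (700, 1200)}

DEVIATION_LIMIT = 1.8  # degrees from fixation
SPEED_LIMIT = 30.0  # deg/s
SACCADE_AMPLITUDE = 1.0  # degrees; larger movements disqualify the trial


@dataclass
class Microsaccade:
    onset: int  # sample index within the fixation window
    duration: int  # samples
    amplitude: float  # degrees
    peak_speed: float  # deg/s


@dataclass
class FixationWindow:
    """One trial's cleaned fixation epoch."""

    kept: bool
    reason: Optional[str] = None
    x: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    #: deviation + speed mask: the drift-analysis sample set
    mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool), repr=False)
    #: deviation-only mask: keeps microsaccades in for event detection
    dev_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool), repr=False)

    def segments(self, min_len: int = 1, which: str = "drift") -> list[tuple[int, int]]:
        """Contiguous [start, stop) runs of retained samples."""
        m = (self.mask if which == "drift" else self.dev_mask).view(np.int8)
        idx = np.flatnonzero(np.diff(np.concatenate(([0], m, [0]))))
        return [(a, b) for a, b in zip(idx[0::2], idx[1::2]) if b - a >= min_len]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def clean_fixation(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray | None = None,
    dt: float = 1.0,
) -> FixationWindow:
    """Apply the fixation-period exclusion rules to one trial window.

    Trials containing a blink (invalid samples) or a saccade of at least
    1° amplitude are dropped entirely.  Otherwise, samples deviating
    more than 1.8° from fixation or faster than 30 deg/s are masked out;
    the two masks are independent, so their order does not matter.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    if not valid.all():
        return FixationWindow(kept=False, reason="blink")

    speed = sliding_velocity(np.column_stack((x, y)), dt=dt)
    fast = np.isfinite(speed) & (speed > SPEED_LIMIT)
    for a, b in _runs(fast):
        amp = float(np.hypot(x[b - 1] - x[a], y[b - 1] - y[a]))
        if amp >= SACCADE_AMPLITUDE:
            return FixationWindow(kept=False, reason="saccade")

    dev_mask = np.ones(len(x), dtype=bool)
    dev_mask[np.hypot(x, y) > DEVIATION_LIMIT] = False
    mask = dev_mask.copy()
    mask[fast] = False
    mask[~np.isfinite(speed)] = False  # velocity undefined at the edges
    return FixationWindow(kept=True, x=x, y=y, mask=mask, dev_mask=dev_mask)


def detect_microsaccades(
    window: FixationWindow,
    dt: float = 1.0,
    lam: float = 6.0,
    min_duration_ms: float = 6.0,
    max_amplitude: float = 1.0,
) -> list[Microsaccade]:
    """Median-based velocity-threshold microsaccade detection.

    Within each retained segment (deviation-masked only — the 30 deg/s
    drift mask would excise the very events being counted), per-axis
    velocity thresholds are set to ``lam`` times a median-based SD
    estimate; samples whose velocity exceeds the elliptic criterion for
    at least ``min_duration_ms`` form an event; events with amplitude
    below ``max_amplitude`` degrees are returned.
    """
    events: list[Microsaccade] = []
    min_run = max(1, int(round(min_duration_ms / dt)))
    for a, b in window.segments(min_len=int(round(20 / dt)), which="events"):
        x, y = window.x[a:b], window.y[a:b]
        # centred 4 ms vector velocity, deg/s
        vx = np.full(len(x), np.nan)
        vy = np.full(len(y), np.nan)
        vx[2:-2] = (x[4:] - x[:-4]) / (4 * dt) * 1000.0
        vy[2:-2] = (y[4:] - y[:-4]) / (4 * dt) * 1000.0
        ok = np.isfinite(vx)
        if ok.sum() < 10:
            continue
        sx = np.sqrt(np.median(vx[ok] ** 2) - np.median(vx[ok]) ** 2)
        sy = np.sqrt(np.median(vy[ok] ** 2) - np.median(vy[ok]) ** 2)
        sx = max(sx, 1e-6)
        sy = max(sy, 1e-6)
        crit = np.zeros(len(x), dtype=bool)
        crit[ok] = (vx[ok] / (lam * sx)) ** 2 + (vy[ok] / (lam * sy)) ** 2 > 1.0
        for s, e in _runs(crit):
            if e - s < min_run:
                continue
            amp = float(np.hypot(x[e - 1] - x[s], y[e - 1] - y[s]))
            if amp >= max_amplitude:
                continue
            speed = np.hypot(vx[s:e], vy[s:e])
            events.append(
                Microsaccade(
                    onset=a + s,
                    duration=e - s,
                    amplitude=amp,
                    peak_speed=float(np.nanmax(speed)),
                )
            )
    return events


def drift_speed(
    window: FixationWindow,
    microsaccades: Sequence[Microsaccade] = (),
    dt: float = 1.0,
    margin_ms: float = 10.0,
    estimator: str = "median",
) -> float:
    """Median (or mean) sample-to-sample drift speed in deg/s.

    Microsaccade episodes (± ``margin_ms``) are excised first.  Returns
    NaN when fewer than 100 ms of drift data remain.
    """
    keep = window.mask.copy()
    margin = int(round(margin_ms / dt))
    for ev in microsaccades:
        lo = max(0, ev.onset - margin)
        hi = min(len(keep), ev.onset + ev.duration + margin)
        keep[lo:hi] = False
    dx = np.diff(window.x)
    dy = np.diff(window.y)
    pair_ok = keep[:-1] & keep[1:]
    speeds = np.hypot(dx[pair_ok], dy[pair_ok]) / dt * 1000.0
    if len(speeds) < int(round(100 / dt)):
        return float("nan")
    return float(np.median(speeds) if estimator == "median" else np.mean(speeds))


def fixation_spectrum(
    x: np.ndarray,
    window: str | tuple[float, float] = "early",
    dt: float = 1.0,
):
    """Amplitude spectrum of detrended horizontal position in one window.

    The 500 ms window ("early" 200–700 ms or "late" 700–1200 ms after
    the cue; ``x`` is the full fixation-window position) is linearly
    detrended and Hann-tapered; the one-sided DFT amplitude is scaled so
    an on-bin sinusoid of amplitude *a* yields a peak of ≈ *a*.  Returns
    ``(freqs_hz, amplitude)`` at 2 Hz resolution for 1000 Hz data.
    """
    if isinstance(window, str):
        lo_ms, hi_ms = SPECTRUM_WINDOWS[window]
    else:
        lo_ms, hi_ms = window
    lo, hi = int(round(lo_ms / dt)), int(round(hi_ms / dt))
    if hi > len(x):
        raise ValueError("fixation window incomplete for this trial")
    seg = np.asarray(x[lo:hi], dtype=float)
    if not np.isfinite(seg).all():
        raise ValueError("fixation window contains missing samples")
    seg = ssig.detrend(seg, type="linear")
    taper = np.hanning(len(seg))
    spec = np.fft.rfft(seg * taper)
    amp = 2.0 * np.abs(spec) / taper.sum()
    freqs = np.fft.rfftfreq(len(seg), d=dt / 1000.0)
    return freqs, amp
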