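"""Pupillometry preprocessing and cue-locked dilation measures.

Pupil size is recorded in arbitrary units (a.u.) at 1000 Hz.  Cleaning
removes instantaneous steps larger than 2.5 a.u./ms, then linearly
interpolates missing runs (blinks) shorter than 500 ms; longer runs stay
missing.  Trial traces are baselined to pupil size at cue onset and
averaged into 20 ms bins over the 1400 ms cue–target interval; the
window-of-interest statistic is the mean dilation 1000–1400 ms after the
cue, where motivational dilation peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PupilTrace", "clean_pupil", "trial_trace", "window_mean"]

BIN_MS = 20
SPAN_MS = 1400
MAX_INTERP_MS = 500.0
MAX_STEP = 2.5  # a.u. per ms


@dataclass
class PupilTrace:
    """Binned, baselined dilation time-course for one trial or average."""

    values: np.ndarray  # a.u. relative to cue-onset baseline
    bin_width: float = float(BIN_MS)
    span: float = float(SPAN_MS)
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != int(self.span / self.bin_width):
            raise ValueError("trace length must equal span / bin_width")

    @property
    def bin_centres(self) -> np.ndarray:
        return self.bin_width * (np.arange(len(self.values)) + 0.5)


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def clean_pupil(
    raw: np.ndarray,
    dt: float = 1.0,
    max_step: float = MAX_STEP,
    max_interp_ms: float = MAX_INTERP_MS,
) -> np.ndarray:
    """Step removal then blink interpolation; returns a cleaned copy.

    Samples whose absolute sample-to-sample change exceeds ``max_step``
    a.u./ms are marked missing, then missing runs shorter than
    ``max_interp_ms`` are linearly bridged from the flanking valid
    samples.  Runs of at least ``max_interp_ms``, and runs touching the
    ends of the array, are left missing.  The operation is idempotent.
    """
    p = np.asarray(raw, dtype=float).copy()
    if len(p) < 2:
        return p
    step = np.abs(np.diff(p)) / dt
    jump = step > max_step
    # a supra-threshold step marks the later sample as artefactual
    p[1:][jump] = np.nan

    missing = ~np.isfinite(p)
    for start, stop in _missing_runs(missing):
        if (stop - start) * dt >= max_interp_ms:
            continue
        if start == 0 or stop == len(p):
            continue  # no flanking value to anchor the bridge
        p[start:stop] = np.interp(
            np.arange(start, stop), [start - 1, stop], [p[start - 1], p[stop]]
        )
    return p


def trial_trace(
    cleaned: np.ndarray,
    cue_index: int,
    dt: float = 1.0,
    bin_ms: float = float(BIN_MS),
    span_ms: float = float(SPAN_MS),
) -> PupilTrace:
    """Baselined 20 ms-binned dilation over 0–1400 ms after the cue.

    The baseline is the mean of the 20 ms bin centred on cue onset
    (single-sample baselines are noise-dominated).  Bins containing only
    missing samples are NaN.
    """
    n_per_bin = int(round(bin_ms / dt))
    n_bins = int(round(span_ms / bin_ms))
    need = cue_index + n_bins * n_per_bin
    if need > len(cleaned):
        raise ValueError("trace does not span the full cue-target interval")
    base_lo = max(0, cue_index - n_per_bin // 2)
    base = np.nanmean(cleaned[base_lo : cue_index + n_per_bin // 2])
    seg = np.asarray(cleaned[cue_index:need], dtype=float).reshape(n_bins, n_per_bin)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(seg, axis=1) - base
    return PupilTrace(values, bin_width=bin_ms, span=span_ms)


def window_mean(trace: PupilTrace, window: tuple[float, float] = (1000.0, 1400.0)) -> float:
    """Mean dilation over bins fully inside the window (ms after cue)."""
    lo, hi = window
    if lo < 0 or hi > trace.span:
        raise ValueError("window must lie inside the trace span")
    edges_lo = trace.bin_width * np.arange(len(trace.values))
    edges_hi = edges_lo + trace.bin_width
    inside = (edges_lo >= lo - 1e-9) & (edges_hi <= hi + 1e-9)
    return float(np.nanmean(trace.values[inside]))
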