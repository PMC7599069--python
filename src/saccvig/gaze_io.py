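"""Plain-text gaze recording format.

A session is stored as two tab-separated files:

* **samples** -- one row per 1 kHz sample: ``t_ms  x_deg  y_deg  pupil  valid``,
  preceded by ``#``-prefixed metadata lines (``participant_id``,
  ``session_label``, ``sampling_rate``).  Positions are in visual degrees,
  pupil size in arbitrary units.  Samples lost to blinks or tracking
  dropout are kept in place with ``valid = 0`` and ``nan`` positions,
  so the time base stays uniform.
* **events** -- one row per trial with the columns of
  :class:`~saccvig.config.TrialEvent`.

The format is vendor-neutral and diff-able; write→read→write is
byte-stable because numbers are serialised at fixed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import TrialEvent

__all__ = ["GazeRecording", "FormatError", "read_recording", "write_recording"]


class FormatError(ValueError):
    """A gaze file violates the documented schema."""


_SAMPLE_COLUMNS = ("t_ms", "x_deg", "y_deg", "pupil", "valid")
_EVENT_COLUMNS = (
    "trial_index",
    "condition",
    "cue_onset",
    "delay",
    "target_onset",
    "target_side",
    "feedback_modality",
    "reward",
    "speed_feedback",
)


@dataclass
class GazeRecording:
    """Uniformly sampled eye position + pupil stream for one session."""

    participant_id: str
    session_label: str
    sampling_rate: float
    t: np.ndarray  # ms
    x: np.ndarray  # degrees
    y: np.ndarray  # degrees
    pupil: np.ndarray  # a.u.
    valid: np.ndarray  # bool
    events: list[TrialEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "pupil", "valid"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"sample column {name!r} has wrong length")
        self.validate()

    @property
    def dt(self) -> float:
        """Sample spacing in ms."""
        return 1000.0 / self.sampling_rate

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise FormatError("timestamps must be strictly increasing")
            if not np.allclose(steps, self.dt, atol=1e-6):
                raise FormatError(
                    "timestamps must be uniform at 1/sampling_rate spacing "
                    "(gaps are represented by invalid filler samples)"
                )
        t0, t1 = (t[0], t[-1]) if len(t) else (0.0, 0.0)
        for ev in self.events:
            if not (t0 <= ev.target_onset <= t1):
                raise FormatError(
                    f"trial {ev.trial_index}: target_onset {ev.target_onset} "
                    f"outside sample range [{t0}, {t1}]"
                )

    def index_at(self, t_ms: float) -> int:
        """Index of the sample at (or just after) time ``t_ms``."""
        return int(np.searchsorted(self.t, t_ms - 1e-9))


def _fmt(v: float, prec: int) -> str:
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return f"{v:.{prec}f}"


def write_recording(rec: GazeRecording, samples_path, events_path) -> None:
    """Serialise a recording to the two-file tab-separated format."""
    with open(samples_path, "w") as fh:
        fh.write(f"# participant_id: {rec.participant_id}\n")
        fh.write(f"# session_label: {rec.session_label}\n")
        fh.write(f"# sampling_rate: {rec.sampling_rate:g}\n")
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for i in range(len(rec.t)):
            fh.write(
                "\t".join(
                    (
                        _fmt(float(rec.t[i]), 1),
                        _fmt(float(rec.x[i]), 5),
                        _fmt(float(rec.y[i]), 5),
                        _fmt(float(rec.pupil[i]), 3),
                        str(int(rec.valid[i])),
                    )
                )
                + "\n"
            )
    with open(events_path, "w") as fh:
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for ev in rec.events:
            fh.write(
                "\t".join(
                    (
                        str(ev.trial_index),
                        ev.condition,
                        _fmt(float(ev.cue_onset), 1),
                        str(int(ev.delay)),
                        _fmt(float(ev.target_onset), 1),
                        ev.target_side,
                        ev.feedback_modality,
                        str(int(ev.reward)),
                        ev.speed_feedback,
                    )
                )
                + "\n"
            )


def _parse_float(tok: str, what: str) -> float:
    try:
        return float(tok)
    except ValueError as exc:
        raise FormatError(f"cannot parse {what}: {tok!r}") from exc


def read_recording(samples_path, events_path) -> GazeRecording:
    """Load and validate a recording; timestamp gaps become invalid samples."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, float, int]] = []
    with open(samples_path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _SAMPLE_COLUMNS:
                    raise FormatError(f"bad sample header: {line!r}")
                header_seen = True
                continue
            tok = line.split("\t")
            if len(tok) != len(_SAMPLE_COLUMNS):
                raise FormatError(f"bad sample row: {line!r}")
            rows.append(
                (
                    _parse_float(tok[0], "t_ms"),
                    _parse_float(tok[1], "x_deg"),
                    _parse_float(tok[2], "y_deg"),
                    _parse_float(tok[3], "pupil"),
                    int(tok[4]),
                )
            )
    if not rows:
        raise FormatError(f"no samples in {samples_path}")
    rate = float(meta.get("sampling_rate", "1000"))
    dt = 1000.0 / rate
    t_raw = np.array([r[0] for r in rows])
    if np.any(np.diff(t_raw) <= 0):
        raise FormatError("timestamps must be strictly increasing")

    # Re-grid onto a uniform time base, inserting invalid fillers in gaps.
    n_total = int(round((t_raw[-1] - t_raw[0]) / dt)) + 1
    t = t_raw[0] + dt * np.arange(n_total)
    idx = np.round((t_raw - t_raw[0]) / dt).astype(int)
    if np.any(np.abs(t_raw - (t_raw[0] + idx * dt)) > 1e-6):
        raise FormatError("timestamps are not on a 1/sampling_rate grid")
    x = np.full(n_total, np.nan)
    y = np.full(n_total, np.nan)
    pupil = np.full(n_total, np.nan)
    valid = np.zeros(n_total, dtype=bool)
    x[idx] = [r[1] for r in rows]
    y[idx] = [r[2] for r in rows]
    pupil[idx] = [r[3] for r in rows]
    valid[idx] = [bool(r[4]) for r in rows]

    events: list[TrialEvent] = []
    with open(events_path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if tuple(line.split("\t")) != _EVENT_COLUMNS:
                    raise FormatError(f"bad event header: {line!r}")
                header_seen = True
                continue
            tok = line.split("\t")
            if len(tok) != len(_EVENT_COLUMNS):
                raise FormatError(f"bad event row: {line!r}")
            try:
                ev = TrialEvent(
                    trial_index=int(tok[0]),
                    condition=tok[1],
                    cue_onset=_parse_float(tok[2], "cue_onset"),
                    delay=int(tok[3]),
                    target_onset=_parse_float(tok[4], "target_onset"),
                    target_side=tok[5],
                    feedback_modality=tok[6],
                    reward=int(tok[7]),
                    speed_feedback=tok[8],
                )
            except ValueError as exc:
                raise FormatError(str(exc)) from exc
            events.append(ev)

    return GazeRecording(
        participant_id=meta.get("participant_id", ""),
        session_label=meta.get("session_label", ""),
        sampling_rate=rate,
        t=t,
        x=x,
        y=y,
        pupil=pupil,
        valid=valid,
        events=events,
    )
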