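"""Main-sequence fits, peak-velocity residuals and per-condition measures.

Peak saccade velocity obeys the main sequence: it grows with amplitude.
To measure motivational invigoration independently of amplitude, peak
velocity is regressed on amplitude by OLS for each participant-session
(pooling all four conditions) and the residual — observed minus
predicted velocity — is the vigour measure.  Positive residuals mean a
saccade was faster than its amplitude predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CONDITION_FACTORS
from .saccades import SaccadeRecord

__all__ = [
    "MainSequenceFit",
    "fit_main_sequence",
    "velocity_residual",
    "endpoint_variability",
    "condition_means",
    "session_residual_table",
]


class DegenerateFitError(ValueError):
    """All amplitudes identical: the main-sequence slope is unidentifiable."""


@dataclass(frozen=True)
class MainSequenceFit:
    """Per participant-session OLS of peak velocity on amplitude."""

    participant_id: str
    session_label: str
    slope: float  # (deg/s) / deg
    intercept: float  # deg/s
    n_trials: int
    r_squared: float

    def predict(self, amplitude) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(amplitude, dtype=float)


def fit_main_sequence(
    saccades: Sequence[SaccadeRecord] | pd.DataFrame,
    participant_id: str = "",
    session_label: str = "",
) -> MainSequenceFit:
    """OLS fit of peak velocity on amplitude across all conditions pooled.

    Accepts the valid saccades of one participant-session, either as
    records or as a table with ``amplitude_deg``/``peak_velocity``
    columns.  Raises :class:`DegenerateFitError` when the amplitudes do
    not vary.
    """
    if isinstance(saccades, pd.DataFrame):
        amp = saccades["amplitude_deg"].to_numpy(dtype=float)
        vel = saccades["peak_velocity"].to_numpy(dtype=float)
    else:
        amp = np.array([s.amplitude for s in saccades], dtype=float)
        vel = np.array([s.peak_velocity for s in saccades], dtype=float)
    if len(amp) < 2:
        raise ValueError("need at least two saccades to fit the main sequence")
    if np.ptp(amp) == 0:
        raise DegenerateFitError("all amplitudes identical")
    res = sps.linregress(amp, vel)
    return MainSequenceFit(
        participant_id=participant_id,
        session_label=session_label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_trials=len(amp),
        r_squared=float(res.rvalue**2),
    )


def velocity_residual(saccade: SaccadeRecord, fit: MainSequenceFit) -> float:
    """Observed minus main-sequence-predicted peak velocity (deg/s)."""
    return float(saccade.peak_velocity - fit.predict(saccade.amplitude))


def endpoint_variability(
    endpoints: np.ndarray | Sequence[tuple[float, float]],
    axis: str = "both",
) -> float:
    """Across-trial scatter of saccade landing positions (degrees).

    Default: root-mean-square Euclidean distance of the bivariate
    endpoints from their centroid.  ``axis="horizontal"`` uses the SD of
    the x coordinate only.
    """
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if len(pts) < 2:
        raise ValueError("need at least two endpoints")
    if axis == "horizontal":
        return float(np.std(pts[:, 0], ddof=1))
    dev = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def session_residual_table(
    saccades: Iterable[SaccadeRecord],
    participant_id: str,
    session_label: str,
    covariate_mode: bool = False,
) -> pd.DataFrame:
    """Valid-saccade table of one session with the vigour residual attached.

    With ``covariate_mode=True`` the ``velocity_residual`` column instead
    carries the raw peak velocity (for analyses that enter amplitude as a
    covariate rather than residualising first); the amplitude column is
    always present so either route is possible downstream.
    """
    valid = [s for s in saccades if s.valid]
    fit = fit_main_sequence(valid, participant_id, session_label)
    rows = []
    for s in valid:
        rows.append(
            {
                "participant_id": participant_id,
                "session_label": session_label,
                "trial_index": s.trial_index,
                "condition": s.condition,
                "amplitude_deg": s.amplitude,
                "peak_velocity": s.peak_velocity,
                "velocity_residual": (
                    s.peak_velocity if covariate_mode else velocity_residual(s, fit)
                ),
                "latency_ms": s.latency,
                "response_time_ms": s.response_time,
                "endpoint_x": s.endpoint[0],
                "endpoint_y": s.endpoint[1],
            }
        )
    return pd.DataFrame(rows)


def condition_means(
    trials: pd.DataFrame,
    measures: Sequence[str],
    participant_col: str = "participant_id",
    session_col: str = "session_label",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Cell-means table: participant × session × contingency × motivation.

    Each condition maps onto the 2×2 factor grid (Performance/Random →
    contingent, 10p/0p → guaranteed; Performance/10p → high motivation,
    Random/0p → low).  Returns one row per cell with the mean of every
    measure; an all-empty cell raises so the caller can drop the
    participant from that analysis explicitly.
    """
    df = trials.copy()
    factors = df[condition_col].map(CONDITION_FACTORS)
    if factors.isna().any():
        bad = sorted(df.loc[factors.isna(), condition_col].unique())
        raise ValueError(f"unknown condition labels: {bad}")
    df["contingency"] = factors.str[0]
    df["motivation"] = factors.str[1]
    keys = [participant_col, session_col, "contingency", "motivation"]
    out = df.groupby(keys, sort=True)[list(measures)].mean().reset_index()
    # verify every participant has a full grid
    n_sessions = df[session_col].nunique()
    expected = 4 * n_sessions
    cells = out.groupby(participant_col).size()
    short = cells[cells < expected]
    if len(short):
        raise ValueError(
            f"participants with empty cells (drop them from this ANOVA): "
            f"{sorted(short.index.tolist())}"
        )
    return out.rename(columns={participant_col: "participant_id", session_col: "session_label"})
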