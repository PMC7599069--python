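"""Synthetic 1000 Hz gaze/pupil generator for the rewarded-saccade task.

The generator emulates the statistical structure every downstream stage
assumes:

* a block schedule of four cue conditions (``Performance``, ``Random``,
  ``10p``, ``0p``) with horizontal targets at ±9.3°;
* main-sequence-governed saccades (peak velocity saturating with
  amplitude) with a minimum-jerk velocity profile, signal-dependent
  motor noise and optional mid-flight negative-feedback correction;
* the adaptive median-of-last-20 reward rule of the Performance
  condition, which yields a ~50% long-run reward rate;
* fixational drift, microsaccades, tremor, blinks, and a cue-locked
  pupil dilation response with AR(1) measurement noise.

Condition effects (vigour offsets in deg/s, latency shifts in ms, pupil
dilation amplitudes) are injected with known ground truth so that the
full pipeline's recovery can be verified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import (
    CONDITIONS,
    DELAYS_MS,
    FEEDBACK_MODALITIES,
    SimulationConfig,
    TrialEvent,
)
from .gaze_io import GazeRecording

__all__ = [
    "build_schedule",
    "adaptive_reward",
    "simulate_saccade",
    "simulate_trials",
    "simulate_session",
    "SimulatedTrial",
]

_PRE_CUE_MS = 500  # fixation before the cue
_POST_TARGET_MS = 1000  # response + feedback epoch after target onset
_MINJERK_AREA = 8.0 / 15.0  # integral of the unit-peak min-jerk speed profile


# ---------------------------------------------------------------------------
# schedule

def build_schedule(config: SimulationConfig, rng: np.random.Generator) -> list[TrialEvent]:
    """Build the ordered trial list: 4 blocks × 12 trials per condition.

    Conditions are randomly ordered within each block, delays are drawn
    uniformly from {1400, 1500, 1600} ms, target side is 50/50, and two
    blocks use each feedback-modality assignment (order randomised).
    Rewards and speed feedback are filled in during simulation.
    """
    n_blocks = 4
    per_block = max(1, config.trials_per_condition // n_blocks)
    modality_order = list(FEEDBACK_MODALITIES) * 2
    rng.shuffle(modality_order)

    events: list[TrialEvent] = []
    clock = 0.0
    index = 0
    for block in range(n_blocks):
        conditions = [c for c in CONDITIONS for _ in range(per_block)]
        rng.shuffle(conditions)
        for cond in conditions:
            delay = int(rng.choice(DELAYS_MS))
            cue = clock + _PRE_CUE_MS
            events.append(
                TrialEvent(
                    trial_index=index,
                    condition=cond,
                    cue_onset=cue,
                    delay=delay,
                    target_onset=cue + delay,
                    target_side="left" if rng.random() < 0.5 else "right",
                    feedback_modality=modality_order[block],
                )
            )
            clock = cue + delay + _POST_TARGET_MS
            index += 1
    return events


def adaptive_reward(rt_history, current_rt: float) -> int:
    """Reward rule of the Performance condition.

    Returns 10 pence if ``current_rt`` beats (is strictly below) the
    median of the last (up to) 20 Performance response times, else 0.
    An empty history is rewarded — the rule needs a reference before it
    can withhold.
    """
    if current_rt <= 0:
        raise ValueError("response time must be positive")
    recent = list(rt_history)[-20:]
    if any(rt <= 0 for rt in recent):
        raise ValueError("response times must be positive")
    if not recent:
        return 10
    return 10 if current_rt < float(np.median(recent)) else 0


# ---------------------------------------------------------------------------
# saccade dynamics

def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Unit-peak minimum-jerk speed profile 16·τ²(1−τ)² on τ ∈ [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 16.0 * tau**2 * (1.0 - tau) ** 2


def saccade_duration_ms(amplitude: float, peak_velocity: float) -> float:
    """Duration implied by amplitude and peak velocity for a min-jerk profile.

    The unit-peak profile has area 8/15, so A = v_peak · D · 8/15.
    """
    return 1000.0 * amplitude / (peak_velocity * _MINJERK_AREA)


def simulate_saccade(
    amplitude: float,
    vigour_offset: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one horizontal saccade; returns positions (deg) at 1 ms steps.

    The noiseless peak velocity is ``vmax·(1−exp(−A/a0)) + vigour_offset``
    and the velocity profile is minimum-jerk scaled to that peak; the
    duration follows from the two.  Each 1 ms velocity command receives
    zero-mean Gaussian noise with SD ``noise_scale·|v|`` (signal-dependent
    motor noise).  With ``feedback_gain > 0`` every step is corrected by
    ``−gain·(actual − nominal position)``, attenuating accumulated noise.

    The returned array starts at 0 and has one sample per ms including
    both endpoints.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    v_peak = config.nominal_peak_velocity(amplitude) + vigour_offset
    if v_peak <= 0:
        raise ValueError("vigour offset drives peak velocity non-positive")
    duration = saccade_duration_ms(amplitude, v_peak)
    n_steps = max(2, int(math.ceil(duration)))
    # evaluate the nominal profile on the exact (possibly fractional) grid
    tgrid = np.minimum(np.arange(n_steps + 1, dtype=float), duration)
    tau = tgrid / duration
    v_nom = v_peak * minimum_jerk_speed(tau) / 1000.0  # deg per ms
    # nominal positions by trapezoidal integration of the exact profile
    x_nom = np.concatenate(([0.0], np.cumsum(0.5 * (v_nom[1:] + v_nom[:-1]) * np.diff(tgrid))))
    x_nom *= amplitude / x_nom[-1]  # exact endpoint

    if config.noise_scale == 0 and config.feedback_gain == 0:
        return x_nom

    noise = config.noise_scale * np.abs(v_nom[:-1]) * rng.standard_normal(n_steps)
    steps = np.diff(x_nom) + noise
    g = config.feedback_gain
    if g == 0:
        return np.concatenate(([0.0], np.cumsum(steps)))
    # x[i+1] = (1-g)·x[i] + (steps[i] + g·x_nom[i]) — an AR(1) recursion
    from scipy.signal import lfilter

    driven = steps + g * x_nom[:-1]
    x_tail = lfilter([1.0], [1.0, -(1.0 - g)], driven)
    return np.concatenate(([0.0], x_tail))


# ---------------------------------------------------------------------------
# trial-level fast path

@dataclass
class SimulatedTrial:
    """One simulated trial's saccade epoch, target-locked.

    ``positions`` holds horizontal eye position at 1 ms steps starting at
    target onset (index 0); the saccade begins ``latency`` ms in.
    Ground-truth fields allow recovery tests.
    """

    condition: str
    target_side: str
    latency: float  # ms
    amplitude: float  # degrees, signed magnitude of the nominal movement
    vigour_offset: float  # deg/s injected on top of the main sequence
    positions: np.ndarray  # (n, 2) x/y degrees


def _draw_latency(config: SimulationConfig, condition: str, rng: np.random.Generator) -> float:
    shift = config.latency_shift + float(config.latency_effects[condition])
    return shift + config.latency_median * math.exp(
        config.latency_sigma * rng.standard_normal()
    )


def simulate_trials(
    config: SimulationConfig,
    session_label: str,
    rng: np.random.Generator,
    participant_effects: dict[str, float] | None = None,
    trials_per_condition: int | None = None,
    post_hold_ms: int = 60,
) -> list[SimulatedTrial]:
    """Simulate target-locked saccade epochs without the full sample stream.

    This is the light-weight path for large simulation studies of the
    vigour measures: it produces, per trial, a short target-locked
    position trace (pre-saccadic fixation, the saccade itself, a brief
    hold) that the saccade detector consumes directly, skipping the
    fixation/pupil channels that do not enter the vigour analysis.
    """
    n = trials_per_condition or config.trials_per_condition
    base = config.vigour_effects_for(session_label)
    eff = {c: base[c] + (participant_effects or {}).get(c, 0.0) for c in CONDITIONS}
    trials: list[SimulatedTrial] = []
    for cond in CONDITIONS:
        for _ in range(n):
            side = "left" if rng.random() < 0.5 else "right"
            sign = -1.0 if side == "left" else 1.0
            amp = max(
                1.5,
                config.amplitude_gain * config.target_eccentricity
                + config.amplitude_sd * rng.standard_normal(),
            )
            latency = _draw_latency(config, cond, rng)
            traj = simulate_saccade(amp, eff[cond], config, rng)
            n_lat = int(round(latency))
            x = np.concatenate(
                (
                    np.zeros(n_lat),
                    sign * traj,
                    np.full(post_hold_ms, sign * traj[-1]),
                )
            )
            pos = np.column_stack((x, np.zeros_like(x)))
            trials.append(
                SimulatedTrial(
                    condition=cond,
                    target_side=side,
                    latency=float(n_lat),
                    amplitude=amp,
                    vigour_offset=eff[cond],
                    positions=pos,
                )
            )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def draw_participant_effects(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Per-participant deviation of each condition's vigour offset (deg/s)."""
    return {c: config.vigour_effect_sd * rng.standard_normal() for c in CONDITIONS}


# ---------------------------------------------------------------------------
# full session

def _pupil_kernel(t_ms: np.ndarray, t_peak: float = 930.0, k: float = 2.0) -> np.ndarray:
    """Unit-peak dilation impulse response (Erlang-style gamma kernel)."""
    t = np.maximum(t_ms, 0.0) / t_peak
    return t**k * np.exp(k * (1.0 - t))


def _ou_drift(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """2-D mean-reverting drift with median sample-to-sample speed ≈ drift_speed."""
    from scipy.signal import lfilter

    # Rayleigh median of |step| is sigma*sqrt(2 ln 2); steps are per ms.
    sigma = (config.drift_speed / 1000.0) / math.sqrt(2.0 * math.log(2.0))
    theta = 0.002  # weak pull to fixation keeps excursions < 1°
    out = np.zeros((n, 2))
    if n > 1:
        steps = sigma * rng.standard_normal((n - 1, 2))
        out[1:] = lfilter([1.0], [1.0, -(1.0 - theta)], steps, axis=0)
    return out


def simulate_session(
    config: SimulationConfig,
    participant_id: str,
    session_label: str,
    rng: np.random.Generator,
):
    """Simulate one full session's 1000 Hz recording.

    Returns ``(recording, ground_truth)`` where ``ground_truth`` is a
    per-trial list of dicts with the injected latency, amplitude and
    vigour offset, plus the session-level effect maps.
    """
    if config.sampling_rate != 1000.0:
        raise ValueError("the generator is defined at 1000 Hz")
    schedule = build_schedule(config, rng)
    participant_effects = draw_participant_effects(config, rng)
    base = config.vigour_effects_for(session_label)
    eff = {c: base[c] + participant_effects[c] for c in CONDITIONS}

    total_ms = int(schedule[-1].target_onset + _POST_TARGET_MS)
    n = total_ms + 1
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    y = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    pupil = np.full(n, config.pupil_baseline + 20.0 * rng.standard_normal())

    # fixational background over the whole session
    drift = _ou_drift(n, config, rng)
    x += drift[:, 0]
    y += drift[:, 1]
    if config.tremor_amp > 0:
        phase = 2.0 * math.pi * rng.random()
        x += config.tremor_amp * np.sin(
            2.0 * math.pi * config.tremor_freq * t / 1000.0 + phase
        )

    # microsaccades: Poisson over the session, redirected toward fixation
    if config.microsaccade_rate > 0:
        n_ms = rng.poisson(config.microsaccade_rate * total_ms / 1000.0)
        for onset in np.sort(rng.uniform(0, total_ms - 40, size=n_ms)):
            i0 = int(onset)
            amp = rng.uniform(0.1, 0.8)
            if math.hypot(x[i0], y[i0]) > 0.3:
                ang = math.atan2(-y[i0], -x[i0]) + 0.3 * rng.standard_normal()
            else:
                ang = rng.uniform(0, 2 * math.pi)
            peak = config.nominal_peak_velocity(amp)
            dur = saccade_duration_ms(amp, peak)
            m = int(math.ceil(dur))
            prof = amp * np.cumsum(minimum_jerk_speed(np.arange(m) / dur))
            prof *= amp / prof[-1]
            if i0 + m < n:
                x[i0 : i0 + m] += math.cos(ang) * prof
                x[i0 + m :] += math.cos(ang) * amp
                y[i0 : i0 + m] += math.sin(ang) * prof
                y[i0 + m :] += math.sin(ang) * amp

    # pupil: cue-locked dilation + slow AR(1) noise
    if config.pupil_noise_sd > 0:
        from scipy.signal import lfilter

        innov = config.pupil_noise_sd * rng.standard_normal(n - 1)
        ar = np.concatenate(([0.0], lfilter([1.0], [1.0, -0.99], innov)))
        pupil = pupil + ar

    events: list[TrialEvent] = []
    truth: list[dict] = []
    perf_rts: list[float] = []
    rts_by_cond: dict[str, list[float]] = {c: [] for c in CONDITIONS}

    for ev in schedule:
        cond = ev.condition
        side_sign = -1.0 if ev.target_side == "left" else 1.0
        amp = max(
            1.5,
            config.amplitude_gain * config.target_eccentricity
            + config.amplitude_sd * rng.standard_normal(),
        )
        latency = float(int(round(_draw_latency(config, cond, rng))))
        traj = simulate_saccade(amp, eff[cond], config, rng)
        i_target = int(ev.target_onset)
        i_on = i_target + int(latency)
        i_off = min(i_on + len(traj) - 1, n - 1)
        seg = traj[: i_off - i_on + 1]
        # ride the saccade on top of the fixational background, then hold
        x[i_on : i_off + 1] += side_sign * seg
        # return saccade to fixation 250 ms after landing (inter-trial epoch)
        i_back = i_off + 250
        landed = side_sign * seg[-1]
        back = simulate_saccade(abs(landed), 0.0, config, rng)
        if i_back + len(back) < n:
            x[i_off + 1 : i_back] += landed
            x[i_back : i_back + len(back)] += landed - np.sign(landed) * back
            # residual error after the return saccade decays to zero
        else:
            x[i_off + 1 :] += landed

        # pupil dilation response to the cue
        i_cue = int(ev.cue_onset)
        span = min(n - i_cue, 2500)
        pupil[i_cue : i_cue + span] += float(
            config.pupil_effect.get(cond, 0.0)
        ) * _pupil_kernel(np.arange(span, dtype=float))

        # outcome bookkeeping
        duration = len(traj) - 1
        rt = latency + duration
        history = rts_by_cond[cond]
        speed_feedback = "fast" if (not history or rt < float(np.median(history[-20:]))) else "slow"
        if cond == "Performance":
            reward = adaptive_reward(perf_rts, rt)
            perf_rts.append(rt)
        elif cond == "Random":
            reward = 10 if rng.random() < 0.5 else 0
        elif cond == "10p":
            reward = 10
        else:
            reward = 0
        history.append(rt)

        events.append(
            TrialEvent(
                trial_index=ev.trial_index,
                condition=cond,
                cue_onset=ev.cue_onset,
                delay=ev.delay,
                target_onset=ev.target_onset,
                target_side=ev.target_side,
                feedback_modality=ev.feedback_modality,
                reward=reward,
                speed_feedback=speed_feedback,
            )
        )
        truth.append(
            {
                "trial_index": ev.trial_index,
                "condition": cond,
                "latency_ms": latency,
                "amplitude_deg": amp,
                "vigour_offset": eff[cond],
                "response_time_ms": rt,
            }
        )

    # blinks: missing position, pupil dip ramps on both edges; blinking is
    # suppressed around the response epoch (people do not blink mid-saccade)
    if config.blink_rate > 0:
        allowed = np.ones(max(1, total_ms - 500), dtype=bool)
        for ev in schedule:
            lo = max(0, int(ev.target_onset) - 100)
            hi = min(len(allowed), int(ev.target_onset) + 700)
            allowed[lo:hi] = False
        candidates = np.flatnonzero(allowed)
        n_blinks = rng.poisson(config.blink_rate * total_ms / 1000.0)
        n_blinks = min(n_blinks, len(candidates))
        for i0 in np.sort(rng.choice(candidates, size=n_blinks, replace=False)):
            i0 = int(i0)
            dur = int(np.clip(rng.normal(config.blink_duration, 40.0), 80, 450))
            i1 = min(i0 + dur, n)
            ramp = 30
            lo = max(0, i0 - ramp)
            hi = min(n, i1 + ramp)
            pupil[lo:i0] -= np.linspace(0, 200, i0 - lo)
            pupil[i1:hi] -= np.linspace(200, 0, hi - i1)
            pupil[i0:i1] = np.nan
            x[i0:i1] = np.nan
            y[i0:i1] = np.nan
            valid[i0:i1] = False

    rec = GazeRecording(
        participant_id=participant_id,
        session_label=session_label,
        sampling_rate=config.sampling_rate,
        t=t,
        x=x,
        y=y,
        pupil=pupil,
        valid=valid,
        events=events,
    )
    ground_truth = {
        "participant_id": participant_id,
        "session_label": session_label,
        "vigour_effects": eff,
        "participant_effects": participant_effects,
        "latency_effects": dict(config.latency_effects),
        "pupil_effect": dict(config.pupil_effect),
        "trials": truth,
    }
    return rec, ground_truth
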