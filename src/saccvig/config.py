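"""Task vocabulary and simulation configuration.

The task has four auditory cue conditions crossed on two factors:

* contingency  -- ``contingent`` (reward depends on response speed) vs
  ``guaranteed`` (reward fixed in advance);
* motivation   -- ``high`` (reward available/likely) vs ``low``.

==============  ============  ==========
condition       contingency   motivation
==============  ============  ==========
Performance     contingent    high
Random          contingent    low
10p             guaranteed    high
0p              guaranteed    low
==============  ============  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

CONDITIONS: tuple[str, ...] = ("Performance", "Random", "10p", "0p")

#: condition -> (contingency level, motivation level)
CONDITION_FACTORS: dict[str, tuple[str, str]] = {
    "Performance": ("contingent", "high"),
    "Random": ("contingent", "low"),
    "10p": ("guaranteed", "high"),
    "0p": ("guaranteed", "low"),
}

SIDES: tuple[str, str] = ("left", "right")
FEEDBACK_MODALITIES: tuple[str, str] = (
    "audio_speed_visual_reward",
    "visual_speed_audio_reward",
)
DELAYS_MS: tuple[int, int, int] = (1400, 1500, 1600)


@dataclass(frozen=True)
class TrialEvent:
    """One trial of the rewarded-saccade task.

    Times are absolute milliseconds on the session clock.  The target
    always appears ``delay`` ms after the cue.
    """

    trial_index: int
    condition: str
    cue_onset: float
    delay: int
    target_onset: float
    target_side: str
    feedback_modality: str
    reward: int = 0
    speed_feedback: str = "slow"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.target_side not in SIDES:
            raise ValueError(f"unknown target side {self.target_side!r}")
        if self.feedback_modality not in FEEDBACK_MODALITIES:
            raise ValueError(f"unknown feedback modality {self.feedback_modality!r}")
        if self.delay not in DELAYS_MS:
            raise ValueError(f"delay must be one of {DELAYS_MS}, got {self.delay}")
        if abs(self.target_onset - (self.cue_onset + self.delay)) > 1e-9:
            raise ValueError("target_onset must equal cue_onset + delay")
        if self.reward not in (0, 10):
            raise ValueError("reward must be 0 or 10 pence")


def _default_vigour_effects() -> dict[str, dict[str, float]]:
    # Additive peak-velocity offsets (deg/s) per session label and condition.
    # The default pattern mirrors a contingent effect ON drug and a
    # guaranteed-reward effect OFF drug.
    return {
        "ON": {"Performance": 15.0, "Random": 0.0, "10p": 0.0, "0p": 0.0},
        "OFF": {"Performance": 0.0, "Random": 0.0, "10p": 15.0, "0p": 0.0},
    }


def _default_latency_effects() -> dict[str, float]:
    return {c: 0.0 for c in CONDITIONS}


def _default_pupil_effect() -> dict[str, float]:
    # a.u. scaling of the dilation response per condition; high-motivation
    # cues dilate slightly more.
    return {"Performance": 30.0, "Random": 20.0, "10p": 30.0, "0p": 10.0}


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic gaze generator.

    Defaults emulate the task geometry (targets at ±9.3°, 1000 Hz,
    4 blocks × 12 trials per condition) and a conventional oculomotor
    main sequence with signal-dependent motor noise.
    """

    n_participants: int = 26
    sessions_per_participant: int = 2
    session_labels: tuple[str, ...] = ("ON", "OFF")
    trials_per_condition: int = 48
    sampling_rate: float = 1000.0  # Hz
    target_eccentricity: float = 9.3  # degrees
    main_sequence_vmax: float = 550.0  # deg/s, saturation velocity
    main_sequence_a0: float = 5.0  # degrees, saturation constant
    vigour_effects: Mapping = field(default_factory=_default_vigour_effects)
    vigour_effect_sd: float = 8.0  # deg/s between-participant SD of each effect
    latency_effects: Mapping[str, float] = field(default_factory=_default_latency_effects)
    latency_shift: float = 80.0  # ms, shifted-lognormal shift
    latency_median: float = 160.0  # ms, lognormal median above the shift
    latency_sigma: float = 0.20  # lognormal shape
    amplitude_sd: float = 0.6  # degrees, trial-to-trial amplitude scatter
    amplitude_gain: float = 0.95  # mean undershoot fraction of eccentricity
    noise_scale: float = 0.10  # SD of velocity-command noise / |v|
    feedback_gain: float = 0.0  # per-ms positional correction gain in [0, 1)
    blink_rate: float = 0.1  # events/s during fixation
    blink_duration: float = 150.0  # ms, mean blink length
    pupil_baseline: float = 1000.0  # a.u.
    pupil_effect: Mapping[str, float] = field(default_factory=_default_pupil_effect)
    pupil_noise_sd: float = 0.5  # a.u., AR(1) innovation SD
    drift_speed: float = 0.5  # deg/s, median fixational drift speed
    microsaccade_rate: float = 1.0  # events/s during fixation
    tremor_freq: float = 80.0  # Hz
    tremor_amp: float = 0.005  # degrees
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 <= self.feedback_gain < 1):
            raise ValueError("feedback_gain must lie in [0, 1)")
        for name in ("blink_rate", "microsaccade_rate", "drift_speed",
                     "tremor_amp", "noise_scale", "vigour_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")
        if self.sessions_per_participant not in (1, 2):
            raise ValueError("sessions_per_participant must be 1 or 2")
        if len(self.session_labels) < self.sessions_per_participant:
            raise ValueError("need a session label per session")
        for label in self.session_labels[: self.sessions_per_participant]:
            effects = self.vigour_effects_for(label)
            if set(effects) != set(CONDITIONS):
                raise ValueError(
                    "vigour_effects must be keyed by exactly the four conditions"
                )
        if set(self.latency_effects) != set(CONDITIONS):
            raise ValueError("latency_effects must be keyed by the four conditions")

    def vigour_effects_for(self, session_label: str) -> dict[str, float]:
        """Resolve the vigour-offset map for one session.

        Accepts either a flat ``{condition: offset}`` map (same for every
        session) or a nested ``{session_label: {condition: offset}}`` map.
        """
        eff = dict(self.vigour_effects)
        if eff and isinstance(next(iter(eff.values())), Mapping):
            return dict(eff.get(session_label, {c: 0.0 for c in CONDITIONS}))
        return {c: float(eff.get(c, 0.0)) for c in CONDITIONS}

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def nominal_peak_velocity(self, amplitude: float) -> float:
        """Main-sequence peak velocity vmax·(1 − exp(−A/a0)) in deg/s."""
        import math

        return self.main_sequence_vmax * (1.0 - math.exp(-amplitude / self.main_sequence_a0))
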