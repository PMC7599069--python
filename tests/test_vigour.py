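"""Main-sequence regression, residuals, endpoint variability, cell means."""

import numpy as np
import pandas as pd
import pytest

from saccvig.config import SimulationConfig
from saccvig.studies import measure_trials
from saccvig.synth import simulate_trials
from saccvig.vigour import (
    DegenerateFitError,
    condition_means,
    endpoint_variability,
    fit_main_sequence,
    velocity_residual,
)


def table(amp, vel):
    return pd.DataFrame({"amplitude_deg": amp, "peak_velocity": vel})


class TestMainSequenceFit:
    def test_collinear_points(self):
        fit = fit_main_sequence(table([5.0, 7.5, 10.0], [300.0, 350.0, 400.0]))
        assert fit.slope == pytest.approx(20.0)
        assert fit.intercept == pytest.approx(200.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ols_against_normal_equations_oracle(self):
        amp = np.array([5.0, 7.5, 10.0, 8.0])
        vel = np.array([300.0, 350.0, 400.0, 380.0])
        # independent closed-form OLS oracle
        sxx = np.sum((amp - amp.mean()) ** 2)
        slope = np.sum((amp - amp.mean()) * (vel - vel.mean())) / sxx
        intercept = vel.mean() - slope * amp.mean()
        fit = fit_main_sequence(table(amp, vel))
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        resid = vel - fit.predict(amp)
        assert resid.sum() == pytest.approx(0.0, abs=1e-9)
        assert resid[3] == pytest.approx(380.0 - (intercept + 8.0 * slope))

    def test_degenerate_amplitudes(self):
        with pytest.raises(DegenerateFitError):
            fit_main_sequence(table([9.0, 9.0, 9.0], [300.0, 310.0, 320.0]))

    def test_noiseless_session_on_main_sequence(self, quiet_config, rng):
        df = measure_trials(simulate_trials(quiet_config, "ON", rng))
        fit = fit_main_sequence(df)
        assert fit.r_squared > 0.99
        resid = df["peak_velocity"] - fit.predict(df["amplitude_deg"])
        # the 4 ms window leaves only a sub-1%-of-peak measurement ripple
        assert np.abs(resid).max() < 3.0

    def test_residuals_orthogonal_to_amplitude(self, rng):
        df = measure_trials(simulate_trials(SimulationConfig(), "ON", rng))
        fit = fit_main_sequence(df)
        resid = (df["peak_velocity"] - fit.predict(df["amplitude_deg"])).to_numpy()
        amp = df["amplitude_deg"].to_numpy()
        n = len(df)
        assert abs(np.dot(resid, amp - amp.mean())) < 1e-8 * n * np.abs(resid).max()


class TestVelocityResidual:
    def test_point_on_line_and_injected_effect_recovery(self, rng):
        cfg = SimulationConfig(
            vigour_effects={"Performance": 15.0, "Random": 0.0, "10p": 0.0, "0p": 0.0},
            vigour_effect_sd=0.0,
        )
        df = measure_trials(simulate_trials(cfg, "ON", rng, trials_per_condition=400))
        fit = fit_main_sequence(df)
        df["resid"] = df["peak_velocity"] - fit.predict(df["amplitude_deg"])
        assert df["resid"].mean() == pytest.approx(0.0, abs=1e-9)
        means = df.groupby("condition")["resid"].mean()
        assert means["Performance"] - means["Random"] == pytest.approx(15.0, abs=1.5)


class TestEndpointVariability:
    def test_identical_endpoints(self):
        assert endpoint_variability([(1.0, 2.0)] * 5) == 0.0

    def test_unit_cross(self):
        pts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
        assert endpoint_variability(pts) == pytest.approx(1.0)

    def test_horizontal_mode(self):
        pts = [(1, 5), (-1, -5), (3, 0), (-3, 0)]
        assert endpoint_variability(pts, axis="horizontal") == pytest.approx(
            np.std([1, -1, 3, -3], ddof=1)
        )

    def test_feedback_reduces_scatter(self):
        rng = np.random.default_rng(3)
        out = {}
        for gain in (0.0, 0.2):
            cfg = SimulationConfig(noise_scale=0.1, feedback_gain=gain,
                                   vigour_effect_sd=0.0)
            df = measure_trials(simulate_trials(cfg, "ON", rng, trials_per_condition=150))
            # endpoint scatter proxy: signed amplitude spread
            out[gain] = df["amplitude_deg"].std()
        assert out[0.2] < out[0.0]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            endpoint_variability([(0.0, 0.0)])


class TestConditionMeans:
    def make_trials(self, n_participants=26, sessions=("ON", "OFF"), per_cell=1):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n_participants):
            for s in sessions:
                for cond in ("Performance", "Random", "10p", "0p"):
                    for _ in range(per_cell):
                        rows.append(
                            {
                                "participant_id": f"P{i:02d}",
                                "session_label": s,
                                "condition": cond,
                                "m": rng.standard_normal(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_single_trial_cell_equals_trial(self):
        df = self.make_trials(n_participants=2, per_cell=1)
        cells = condition_means(df, ["m"])
        merged = df.merge(
            cells,
            left_on=["participant_id", "session_label"],
            right_on=["participant_id", "session_label"],
        )
        row = cells[
            (cells.participant_id == "P00")
            & (cells.session_label == "ON")
            & (cells.contingency == "guaranteed")
            & (cells.motivation == "high")
        ]
        src = df[
            (df.participant_id == "P00") & (df.session_label == "ON") & (df.condition == "10p")
        ]
        assert row["m"].iloc[0] == pytest.approx(src["m"].iloc[0])

    def test_full_design_has_208_rows(self):
        cells = condition_means(self.make_trials(), ["m"])
        assert len(cells) == 208
        assert set(cells.contingency) == {"contingent", "guaranteed"}
        assert set(cells.motivation) == {"high", "low"}

    def test_balanced_null_cell_effects_near_zero(self):
        df = self.make_trials(n_participants=40, per_cell=20)
        cells = condition_means(df, ["m"])
        effects = cells.groupby(["contingency", "motivation"])["m"].mean() - cells["m"].mean()
        assert np.abs(effects).max() < 0.05

    def test_missing_cell_raises(self):
        df = self.make_trials(n_participants=3)
        df = df[~((df.participant_id == "P01") & (df.condition == "10p"))]
        with pytest.raises(ValueError, match="P01"):
            condition_means(df, ["m"])

    def test_unknown_condition_rejected(self):
        df = self.make_trials(n_participants=2)
        df.loc[df.index[0], "condition"] = "Mystery"
        with pytest.raises(ValueError, match="Mystery"):
            condition_means(df, ["m"])


def test_covariate_mode_agrees_in_sign(rng):
    """Residualising vs amplitude-as-covariate: same sign of the reward effect."""
    cfg = SimulationConfig(
        vigour_effects={"Performance": 15.0, "Random": 0.0, "10p": 0.0, "0p": 0.0},
        vigour_effect_sd=0.0,
    )
    df = measure_trials(simulate_trials(cfg, "ON", rng, trials_per_condition=300))
    fit = fit_main_sequence(df)
    resid_effect = (
        df.assign(r=df.peak_velocity - fit.predict(df.amplitude_deg))
        .groupby("condition")["r"]
        .mean()
    )
    # covariate route: regress velocity on amplitude + condition indicator
    d = df.assign(is_perf=(df.condition == "Performance").astype(float))
    X = np.column_stack([np.ones(len(d)), d.amplitude_deg, d.is_perf])
    beta = np.linalg.lstsq(X, d.peak_velocity.to_numpy(), rcond=None)[0]
    assert np.sign(beta[2]) == np.sign(
        resid_effect["Performance"] - resid_effect[["Random", "10p", "0p"]].mean()
    )
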