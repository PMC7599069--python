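"""Fixation-period cleaning, microsaccades, drift speed, tremor spectra."""

import numpy as np
import pytest

from saccvig.config import SimulationConfig
from saccvig.fixation import (
    clean_fixation,
    detect_microsaccades,
    drift_speed,
    fixation_spectrum,
)
from saccvig.synth import minimum_jerk_speed, saccade_duration_ms, simulate_session


def quiet_drift(n=1400, speed=0.5, seed=0):
    """Bounded random-walk fixation with a given median sample speed."""
    rng = np.random.default_rng(seed)
    sigma = (speed / 1000.0) / np.sqrt(2 * np.log(2))
    steps = sigma * rng.standard_normal((n, 2))
    pos = np.cumsum(steps, axis=0)
    pos -= pos.mean(axis=0)  # keep within the deviation limit
    return pos[:, 0], pos[:, 1]


def inject_microsaccade(x, y, onset, amplitude=0.5, angle=0.0):
    peak = 550.0 * (1 - np.exp(-amplitude / 5.0))
    dur = saccade_duration_ms(amplitude, peak)
    m = int(np.ceil(dur))
    prof = np.cumsum(minimum_jerk_speed(np.arange(m) / dur))
    prof *= amplitude / prof[-1]
    x[onset : onset + m] += np.cos(angle) * prof
    x[onset + m :] += np.cos(angle) * amplitude
    y[onset : onset + m] += np.sin(angle) * prof
    y[onset + m :] += np.sin(angle) * amplitude
    return x, y


class TestCleanFixation:
    def test_quiet_trial_fully_retained(self):
        x, y = quiet_drift()
        win = clean_fixation(x, y)
        assert win.kept
        # only the velocity-window edges are undefined
        assert win.mask[2:-2].all()

    def test_saccade_drops_trial(self):
        x, y = quiet_drift()
        inject_microsaccade(x, y, 700, amplitude=2.0)
        win = clean_fixation(x, y)
        assert not win.kept and win.reason == "saccade"

    def test_blink_drops_trial(self):
        x, y = quiet_drift()
        x[300:350] = np.nan
        win = clean_fixation(x, y)
        assert not win.kept and win.reason == "blink"

    def test_deviant_sample_removed(self):
        x, y = quiet_drift(speed=0.1)
        x[:] *= 0.01
        x += np.where(np.arange(len(x)) == 700, 0.0, 0.0)
        x[680:720] += 2.0  # slow square excursion beyond 1.8°
        # ramp the edges so no 30 deg/s crossing of >=1° occurs
        x[660:680] += np.linspace(0, 2.0, 20)
        x[720:740] += np.linspace(2.0, 0, 20)
        win = clean_fixation(x, y)
        if win.kept:
            assert not win.mask[690:710].any()

    def test_masks_commute(self):
        x, y = quiet_drift(speed=3.0, seed=3)
        x[500:520] += np.linspace(0, 2.2, 20)
        x[520:540] += np.linspace(2.2, 0, 20)
        win = clean_fixation(x, y)
        if win.kept:
            from saccvig.fixation import DEVIATION_LIMIT, SPEED_LIMIT
            from saccvig.saccades import sliding_velocity

            speed = sliding_velocity(np.column_stack((x, y)))
            m_dev = np.hypot(x, y) <= DEVIATION_LIMIT
            m_spd = ~(np.isfinite(speed) & (speed > SPEED_LIMIT)) & np.isfinite(speed)
            assert np.array_equal(win.mask, m_dev & m_spd)
            assert np.array_equal(win.mask, m_spd & m_dev)


class TestMicrosaccades:
    def test_no_events_in_pure_drift(self):
        x, y = quiet_drift(speed=0.3, seed=1)
        win = clean_fixation(x, y)
        assert detect_microsaccades(win) == []

    def test_single_injected_event_recovered(self):
        x, y = quiet_drift(speed=0.3, seed=2)
        inject_microsaccade(x, y, 700, amplitude=0.5)
        win = clean_fixation(x, y)
        assert win.kept
        events = detect_microsaccades(win)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(0.5, abs=0.1)
        assert abs(events[0].onset - 700) < 10

    def test_poisson_rate_recovered_from_generator(self):
        cfg = SimulationConfig(
            trials_per_condition=12,
            microsaccade_rate=1.5,
            blink_rate=0.0,
            tremor_amp=0.0,
            drift_speed=0.3,
            noise_scale=0.0,
        )
        rec, _ = simulate_session(cfg, "P01", "ON", np.random.default_rng(6))
        counts = []
        for ev in rec.events:
            i0 = rec.index_at(ev.cue_onset)
            win = clean_fixation(rec.x[i0 : i0 + 1400], rec.y[i0 : i0 + 1400])
            if win.kept:
                counts.append(len(detect_microsaccades(win)))
        assert len(counts) > 20
        expected = 1.5 * 1.4
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.3


class TestDriftSpeed:
    def test_random_walk_speed_recovered(self):
        speeds = []
        for seed in range(8):
            x, y = quiet_drift(n=1400, speed=0.5, seed=seed)
            win = clean_fixation(x, y)
            speeds.append(drift_speed(win))
        assert np.nanmean(speeds) == pytest.approx(0.5, rel=0.15)

    def test_stationary_eye_zero(self):
        win = clean_fixation(np.zeros(1400), np.zeros(1400))
        assert drift_speed(win) == 0.0

    def test_microsaccade_excision_stabilises_estimate(self):
        x, y = quiet_drift(speed=0.5, seed=9)
        base = drift_speed(clean_fixation(x, y))
        x2, y2 = x.copy(), y.copy()
        inject_microsaccade(x2, y2, 400, 0.5)
        inject_microsaccade(x2, y2, 900, 0.4, angle=np.pi)
        win2 = clean_fixation(x2, y2)
        events = detect_microsaccades(win2)
        assert len(events) >= 1
        with_excision = drift_speed(win2, events)
        assert with_excision == pytest.approx(base, rel=0.1)

    def test_insufficient_data_is_nan(self):
        x, y = quiet_drift(n=1400, speed=0.5, seed=4)
        win = clean_fixation(x, y)
        win.mask[80:] = False
        assert np.isnan(drift_speed(win))


class TestSpectrum:
    def test_sinusoid_peak_amplitude(self):
        t = np.arange(1400, dtype=float)
        a = 0.05
        x = a * np.sin(2 * np.pi * 40.0 * t / 1000.0)
        freqs, amp = fixation_spectrum(x, "early")
        k = np.argmin(np.abs(freqs - 40.0))
        assert freqs[k] == pytest.approx(40.0)
        assert amp[k] == pytest.approx(a, rel=0.05)
        assert freqs[1] - freqs[0] == pytest.approx(2.0)

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        spectra = []
        for _ in range(200):
            _, amp = fixation_spectrum(rng.standard_normal(1400), "late")
            spectra.append(amp)
        mean = np.mean(spectra, axis=0)[5:-5]
        assert mean.std() / mean.mean() < 0.1

    def test_incomplete_window_rejected(self):
        with pytest.raises(ValueError):
            fixation_spectrum(np.zeros(600), "late")

    def test_tremor_detected_by_cluster_permutation(self):
        """Spectral difference with vs without tremor forms a significant
        cluster at the tremor frequency across simulated participants."""
        from saccvig.stats import cluster_permutation

        rng = np.random.default_rng(11)
        diffs = []
        t = np.arange(1400, dtype=float)
        for _ in range(12):
            base_x, _ = quiet_drift(speed=0.4, seed=int(rng.integers(1 << 30)))
            phase = rng.uniform(0, 2 * np.pi)
            tremor = 0.02 * np.sin(2 * np.pi * 80.0 * t / 1000.0 + phase)
            _, a1 = fixation_spectrum(base_x + tremor, "early")
            _, a0 = fixation_spectrum(base_x, "early")
            diffs.append(a1 - a0)
        res = cluster_permutation(np.vstack(diffs), n_perm=500, rng=rng)
        sig = res.significant
        assert sig
        freqs, _ = fixation_spectrum(np.zeros(1400), "early")
        covered = np.concatenate([c.indices for c in sig])
        assert any(abs(freqs[i] - 80.0) <= 2.0 for i in covered)
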