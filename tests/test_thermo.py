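"""Temperature processing: deviations, circadian filter, episode alignment."""

import numpy as np
import pytest

from aviasomn import NREM, REM, WAKE, SimSleepParams, SimTbrParams, \
    simulate_state_sequence, synthesize_tbr
from aviasomn.io import Hypnogram
from aviasomn.metrics import segment_episodes
from aviasomn.protocol import Protocol, study_protocol
from aviasomn.thermo import (
    CircadianFilterSpec,
    align_episodes,
    bootstrap_night_difference,
    butter_highpass_gain,
    circadian_filter,
    minute_deviation,
    resample_to_1s,
)


class TestMinuteDeviation:
    def test_constant_series_deviates_zero(self):
        dev = minute_deviation(np.full(3600, 40.0), 1.0, slice(0, 3600))
        assert np.allclose(dev, 0.0)

    def test_cold_minute_arithmetic(self):
        """Baseline mean 40 degC, one minute at 38.6: deviation -1.4."""
        x = np.full(7200, 40.0)
        x[3600:3660] = 38.6
        dev = minute_deviation(x, 1.0, slice(0, 3600))
        assert dev[60] == pytest.approx(-1.4)
        assert dev[0] == pytest.approx(0.0)

    def test_synthetic_cold_night_recovers_configured_depression(self):
        """Cold-night plateau deviation minus the baseline-night value in
        the same clock window recovers the configured depression within
        0.15 degC."""
        proto = study_protocol()
        labels = simulate_state_sequence(proto, SimSleepParams(seed=31))
        tbr = synthesize_tbr(labels, SimTbrParams(cold_depression_degC=1.1),
                             proto, seed=31)
        spd = int(proto.day_s)
        dev = minute_deviation(tbr, 1.0, slice(0, spd))
        lo, hi = proto.cold_plateau_interval_s()
        lo_min = int(lo) // 60 + 90  # let the 30-min lag settle
        hi_min = int(hi) // 60
        cold = dev[lo_min:hi_min].mean()
        base = dev[lo_min - 1440:hi_min - 1440].mean()
        assert abs((cold - base) - (-1.1)) < 0.15


class TestCircadianFilter:
    def test_cutoff_frequency_is_23p15_hours(self):
        assert CircadianFilterSpec().cutoff_period_h == pytest.approx(
            23.15, abs=0.01
        )

    def test_24h_sinusoid_attenuation_matches_analytic_response(self):
        """Measured amplitude of a filtered 24-h sinusoid equals the
        squared first-order Butterworth magnitude (the zero-phase filter
        applies |H| twice) within 5%."""
        spec = CircadianFilterSpec()
        n = 10 * 86400
        t = np.arange(n, dtype=float)
        x = np.sin(2 * np.pi * t / 86400.0)
        y = circadian_filter(x, spec)
        mid = slice(4 * 86400, 6 * 86400)  # away from edge transients
        measured = (y[mid].max() - y[mid].min()) / 2.0
        predicted = butter_highpass_gain(1.0 / 86400.0, spec)
        assert abs(measured - predicted) / predicted < 0.05

    def test_60s_pulse_height_preserved(self):
        """A 60-s pulse rides far above the cutoff: its height over the
        local baseline (the episode-alignment convention) passes at
        >= 99.9%."""
        spec = CircadianFilterSpec()
        n = 5 * 86400
        x = np.zeros(n)
        mid = n // 2
        x[mid:mid + 60] = 1.0
        y = circadian_filter(x, spec)
        height = y[mid:mid + 60].max() - y[mid - 3600:mid - 60].mean()
        assert height >= 0.999

    def test_linearity(self):
        rng = np.random.default_rng(3)
        n = 4 * 86400
        x = rng.standard_normal(n)
        y = np.sin(2 * np.pi * np.arange(n) / 5000.0)
        spec = CircadianFilterSpec()
        lhs = circadian_filter(2.0 * x + 3.0 * y, spec)
        rhs = 2.0 * circadian_filter(x, spec) + 3.0 * circadian_filter(y, spec)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_short_segment_falls_back_to_mean_subtraction(self):
        x = np.arange(1000.0)
        with pytest.warns(UserWarning, match="mean subtraction"):
            y = circadian_filter(x, CircadianFilterSpec())
        assert y.mean() == pytest.approx(0.0, abs=1e-9)

    def test_long_nan_gap_splits_series(self):
        n = 8 * 86400
        x = np.sin(2 * np.pi * np.arange(n) / 3000.0)
        x[4 * 86400:4 * 86400 + 1000] = np.nan  # 16-min gap
        y = circadian_filter(x, CircadianFilterSpec())
        gap = slice(4 * 86400, 4 * 86400 + 1000)
        assert np.isnan(y[gap]).all()
        assert np.isfinite(y[:4 * 86400]).all()

    def test_literal_lowpass_mode_keeps_slow_component(self):
        spec = CircadianFilterSpec(mode="lowpass")
        n = 10 * 86400
        x = np.sin(2 * np.pi * np.arange(n) / 86400.0)
        y = circadian_filter(x, spec)
        mid = slice(4 * 86400, 6 * 86400)
        measured = (y[mid].max() - y[mid].min()) / 2.0
        assert measured == pytest.approx(
            butter_highpass_gain(1.0 / 86400.0, spec), rel=0.05
        )


def _episodes_and_mask(labels, proto):
    hyp = Hypnogram(labels=labels)
    eps = segment_episodes(hyp, split_at_epochs=proto.phase_boundaries_epochs())
    return eps, hyp.artifact_mask


class TestAlignment:
    def test_single_episode_curve_is_its_relative_trace(self):
        proto = Protocol(day_labels=("baseline",), day_hours=2.0)
        labels = np.full(proto.n_epochs, WAKE, dtype=np.int8)
        start = proto.n_epochs * 3 // 4
        labels[start:start + 5] = REM  # one 20-s REM episode at night
        tbr = np.linspace(40.0, 41.0, int(proto.total_s))
        eps, mask = _episodes_and_mask(labels, proto)
        curves = align_episodes(tbr, eps, mask, proto)
        rem = [c for c in curves if c.state == "REM"]
        assert len(rem) == 1
        t0 = start * 4
        expected = tbr[t0:t0 + 21] - tbr[t0]
        assert np.allclose(rem[0].mean_degC, expected)
        assert rem[0].mean_degC[0] == 0.0

    def test_t0_anchoring_and_n_monotone(self):
        proto = study_protocol()
        labels = simulate_state_sequence(proto, SimSleepParams(seed=8))
        tbr = synthesize_tbr(labels, SimTbrParams(), proto, seed=8)
        eps, mask = _episodes_and_mask(labels, proto)
        curves = align_episodes(tbr, eps, mask, proto)
        assert curves
        for c in curves:
            assert c.mean_degC[0] == 0.0
            assert np.all(np.diff(c.n) <= 0)

    def test_artifact_episodes_excluded(self):
        proto = Protocol(day_labels=("baseline",), day_hours=2.0)
        labels = np.full(proto.n_epochs, WAKE, dtype=np.int8)
        start = proto.n_epochs * 3 // 4
        labels[start:start + 5] = REM
        tbr = np.linspace(40.0, 41.0, int(proto.total_s))
        eps, mask = _episodes_and_mask(labels, proto)
        mask = mask.copy()
        mask[start + 2] = True
        curves = align_episodes(tbr, eps, mask, proto)
        assert not [c for c in curves if c.state == "REM"]

    def test_rem_drift_recovered_reversion_off(self):
        """With mean reversion disabled, the short-stratum REM curve
        slope over 0-20 s recovers the configured +0.004 degC/s drift
        within 15%; the Wake curve recovers its negative drift.

        Run on a single night: without reversion the integrated drift is
        non-stationary over multi-day runs, so the detrending stage uses
        its documented short-series mean-subtraction fallback.
        """
        proto = Protocol(day_labels=("baseline",), day_hours=24.0)
        params = SimTbrParams(reversion_tau_s=float("inf"),
                              noise_sd_degC=0.02)
        labels = simulate_state_sequence(proto, SimSleepParams(seed=12))
        tbr = synthesize_tbr(labels, params, proto, seed=12)
        with pytest.warns(UserWarning, match="mean subtraction"):
            filt = circadian_filter(tbr, CircadianFilterSpec())
        eps, mask = _episodes_and_mask(labels, proto)
        curves = align_episodes(filt, eps, mask, proto)
        slopes = {}
        for st, drift in (("REM", 0.004), ("WAKE", -0.003)):
            cs = [c for c in curves if c.state == st and c.stratum == "short"]
            stack_t = np.concatenate([c.t_s[:21] for c in cs])
            stack_v = np.concatenate([
                np.where(c.n[:21] > 0, c.mean_degC[:21], np.nan) for c in cs
            ])
            w = np.concatenate([c.n[:21] for c in cs]).astype(float)
            ok = np.isfinite(stack_v)
            slope = np.polyfit(stack_t[ok], stack_v[ok], 1, w=w[ok])[0]
            slopes[st] = slope
            assert abs(slope - drift) / abs(drift) < 0.15, (st, slope)
        assert slopes["REM"] > 0 > slopes["WAKE"]

    def test_wake_cooling_direction_consistent(self):
        """Wake curves end below zero in >= 95% of replicates."""
        proto = Protocol(day_labels=("baseline",), day_hours=8.0)
        neg = 0
        n_rep = 20
        for seed in range(n_rep):
            labels = simulate_state_sequence(proto, SimSleepParams(seed=seed))
            tbr = synthesize_tbr(labels, SimTbrParams(), proto, seed=seed)
            filt = circadian_filter(tbr, CircadianFilterSpec())
            eps, mask = _episodes_and_mask(labels, proto)
            curves = align_episodes(filt, eps, mask, proto)
            wake = [c for c in curves
                    if c.state == "WAKE" and c.stratum == "short"]
            vals = [c.mean_degC[15] for c in wake if c.n[15] > 3]
            if vals and np.mean(vals) < 0:
                neg += 1
        assert neg / n_rep >= 0.95

    def test_driftfree_generator_curves_near_zero_after_filtering(self):
        """Detrending necessity: with negligible drifts the filtered
        curves sit within noise of zero (mean |curve| < 3 SEM)."""
        proto = study_protocol()
        params = SimTbrParams(
            drift_degC_per_s={REM: 1e-9, WAKE: -1e-9, NREM: 0.0},
            noise_sd_degC=0.02,
        )
        labels = simulate_state_sequence(proto, SimSleepParams(seed=14))
        tbr = synthesize_tbr(labels, params, proto, seed=14)
        filt = circadian_filter(tbr, CircadianFilterSpec())
        eps, mask = _episodes_and_mask(labels, proto)
        curves = align_episodes(filt, eps, mask, proto)
        for c in curves:
            if c.stratum != "short":
                continue
            sel = c.n > 10
            sel[0] = False  # t=0 is identically zero
            if sel.sum() < 5:
                continue
            mean_abs = np.mean(np.abs(c.mean_degC[sel]))
            mean_sem = np.mean(c.sem_degC[sel])
            assert mean_abs < 3.0 * mean_sem, (c.state, c.night)


def test_resample_is_identity_at_1hz():
    x = np.arange(100.0)
    assert np.array_equal(resample_to_1s(x, 1.0), x)


def test_resample_interpolates_slower_series():
    x = np.arange(0.0, 100.0, 2.0)  # 0.5 Hz
    y = resample_to_1s(x, 0.5)
    assert y[0] == 0.0
    assert y[1] == pytest.approx(1.0)


def test_bootstrap_night_difference_brackets_known_offset():
    """Cold-night Wake cooling is steeper than baseline by construction
    when the generator's cold-night drift is amplified."""
    proto = study_protocol()
    labels = simulate_state_sequence(proto, SimSleepParams(seed=17))
    tbr = synthesize_tbr(labels, SimTbrParams(), proto, seed=17)
    filt = circadian_filter(tbr, CircadianFilterSpec())
    hyp = Hypnogram(labels=labels)
    eps = segment_episodes(hyp, split_at_epochs=proto.phase_boundaries_epochs())
    out = bootstrap_night_difference(
        filt, eps, hyp.artifact_mask, proto,
        state=REM, night_a="baseline", night_b="cold", t_s=16.0, seed=4
    )
    assert out["ci_low"] <= out["difference_degC"] <= out["ci_high"]
    assert out["n_a"] > 10 and out["n_b"] > 10
    # identical generator parameters on both nights: CI straddles zero
    assert out["ci_low"] < 0 < out["ci_high"]
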