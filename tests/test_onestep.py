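import dataclasses

import numpy as np
import pandas as pd
import pytest

from onestepqtc import (
    AnimalParams,
    OneStepConfig,
    SlopeFitError,
    delta_delta_qtc,
    delta_qtc,
    hourly_slope,
    hourly_slopes,
    onestep_qtc,
    pool_hours,
    simulate_beats,
    simulate_hr_track,
)
from onestepqtc.preprocess import minute_pairs, window_pairs


def _hour_pairs(hr, qt, start_minute=0):
    return pd.DataFrame({
        "minute_index": start_minute + np.arange(len(hr)),
        "hr": hr, "qt": qt,
        "n_beats": np.full(len(hr), 70, dtype=int)})


class TestHourlySlope:
    def test_exact_line(self):
        hr = 80.0 + 10.0 * np.sin(np.arange(60) / 3.0)
        est = hourly_slope(_hour_pairs(hr, 280.0 - 0.4 * hr))
        assert est.beta == pytest.approx(-0.4, abs=1e-12)
        assert est.model == "onestep"

    def test_flat_hr_raises(self):
        hr = np.full(60, 80.0)
        with pytest.raises(SlopeFitError, match="spread"):
            hourly_slope(_hour_pairs(hr, np.full(60, 250.0)))

    def test_too_few_minutes_raises(self):
        hr = 80.0 + np.arange(20.0)
        with pytest.raises(SlopeFitError, match="minute pairs"):
            hourly_slope(_hour_pairs(hr, 250.0 - 0.5 * hr))

    def test_matches_normal_equations_oracle(self, rng):
        hr = 80.0 + rng.normal(0, 8, 60)
        qt = 250.0 - 0.6 * (hr - 80.0) + rng.normal(0, 3, 60)
        est = hourly_slope(_hour_pairs(hr, qt))
        xc = hr - hr.mean()
        assert est.beta == pytest.approx(
            float(xc @ qt / (xc @ xc)), rel=1e-9)

    def test_fallback_uses_session_median_and_flags(self):
        frames = []
        for h, slope in ((0, -0.3), (1, -0.5), (2, -0.7)):
            hr = 80.0 + 8.0 * np.sin(np.arange(60) / 2.0)
            frames.append(_hour_pairs(hr, 250.0 + slope * (hr - 80.0),
                                      start_minute=60 * h))
        # hour 3: flat HR -> fallback
        frames.append(_hour_pairs(np.full(60, 90.0), np.full(60, 245.0),
                                  start_minute=180))
        minutes = pd.concat(frames, ignore_index=True)
        slopes = hourly_slopes(minutes, dose_time_s=0.0)
        flagged = slopes[slopes["fallback"]]
        assert list(flagged["hour_index"]) == [4]
        assert flagged["beta"].iloc[0] == pytest.approx(-0.5)  # median

    def test_estimator_unbiased_without_hysteresis(self, rng):
        """Slope recovery bias < 0.02 ms/bpm when QT adapts instantly."""
        params = AnimalParams(beta_true=-0.7, autonomic_sd=8.0,
                              circadian_amp=0.0, qt_autonomic_sd=0.0,
                              qt_noise_sd=2.0, hysteresis_tau=1e-3)
        errs = []
        for _ in range(200):
            track = simulate_hr_track(params, 3601, seed=rng)
            if np.std(track) < 5.0:
                continue
            beats = simulate_beats(track, params, seed=rng)
            est = hourly_slope(minute_pairs(beats))
            errs.append(est.beta - params.beta_true)
        assert len(errs) > 150
        assert abs(np.mean(errs)) < 0.02

    def test_hysteresis_attenuation_is_bounded(self, rng):
        """The default 90 s QT lag shrinks |beta| by a bounded factor."""
        params = AnimalParams(beta_true=-0.5, circadian_amp=0.0,
                              qt_autonomic_sd=0.0, qt_noise_sd=0.0)
        betas = []
        for _ in range(40):
            track = simulate_hr_track(params, 3601, seed=rng)
            beats = simulate_beats(track, params, seed=rng)
            betas.append(hourly_slope(minute_pairs(beats)).beta)
        ratio = np.mean(betas) / params.beta_true
        assert 0.78 < ratio < 0.95


class TestOneStepQtc:
    def _windows(self, hr, qt):
        n = len(hr)
        return pd.DataFrame({"window_index": np.arange(n), "hr": hr,
                             "qt": qt, "n_beats": np.full(n, 400)})

    def test_reference_identity_at_80_bpm(self):
        slopes = pd.DataFrame({"hour_index": [1], "beta": [-0.9],
                               "fallback": [False]})
        qtc = onestep_qtc(self._windows([80.0], [260.0]), slopes,
                          dose_time_s=0.0)
        assert qtc["qtc"].iloc[0] == 260.0

    def test_complete_hour_yields_12_values(self, quiet_params, rng):
        track = simulate_hr_track(
            dataclasses.replace(quiet_params, autonomic_sd=6.0),
            3601, seed=rng)
        beats = simulate_beats(track, quiet_params, seed=rng)
        minutes, windows = minute_pairs(beats), window_pairs(beats)
        slopes = hourly_slopes(minutes, dose_time_s=0.0)
        assert len(onestep_qtc(windows, slopes, dose_time_s=0.0)) == 12

    def test_corrects_to_generative_truth(self, rng):
        """QTc tracks qt - beta_true*(hr-80) when noise channels are off."""
        params = AnimalParams(beta_true=-0.55, autonomic_sd=8.0,
                              qt_autonomic_sd=0.0, qt_noise_sd=1.0,
                              hysteresis_tau=1e-3)
        track = simulate_hr_track(params, 4 * 3600 + 1, seed=rng)
        beats = simulate_beats(track, params, seed=rng)
        minutes, windows = minute_pairs(beats), window_pairs(beats)
        slopes = hourly_slopes(minutes, dose_time_s=0.0)
        qtc = onestep_qtc(windows, slopes, dose_time_s=0.0)
        truth = (windows["qt"].to_numpy()
                 - params.beta_true * (windows["hr"].to_numpy() - 80.0))
        assert np.mean(np.abs(qtc["qtc"].to_numpy() - truth)) < 1.0


class TestDeltas:
    def _qtc_frame(self, hours=(0, 1, 2), qtc=250.0):
        w = np.arange(-12, 12 * (len(hours) - 1))
        return pd.DataFrame({
            "window_rel": w, "hour_index": w // 12 + 1,
            "qtc": np.full(len(w), float(qtc)),
            "hr": np.full(len(w), 80.0),
            "n_beats": np.full(len(w), 400)})

    def test_identical_sessions_give_zero(self):
        v = self._qtc_frame()
        d = delta_qtc(v, v.copy())
        assert np.all(d["dqtc"] == 0.0)

    def test_constant_offset_recovered(self):
        v = self._qtc_frame()
        t = v.copy()
        t["qtc"] = t["qtc"] + 10.0
        d = delta_qtc(v, t)
        assert np.all(d["dqtc"] == 10.0)

    def test_unmatched_windows_dropped(self):
        v = self._qtc_frame()
        t = self._qtc_frame().iloc[:-5]
        assert len(delta_qtc(v, t)) == len(t)

    def test_equal_baselines_make_double_delta_equal_single(self):
        v = self._qtc_frame()
        t = v.copy()
        post = t["hour_index"] >= 1
        t.loc[post, "qtc"] += 7.0  # baselines (hour 0) stay equal
        dd = delta_delta_qtc(v, t)
        d = delta_qtc(v, t)
        np.testing.assert_allclose(dd["dqtc"], d["dqtc"])

    def test_vehicle_baseline_shift_moves_double_delta(self):
        v = self._qtc_frame()
        t = v.copy()
        v_shifted = v.copy()
        base = v_shifted["hour_index"] == 0
        v_shifted.loc[base, "qtc"] += 5.0
        dd = delta_delta_qtc(v_shifted, t)
        post = dd[dd["hour_index"] >= 1]
        d_post = delta_qtc(v_shifted, t).query("hour_index >= 1")
        np.testing.assert_allclose(post["dqtc"],
                                   d_post["dqtc"].to_numpy() + 5.0)

    def test_missing_baseline_errors(self):
        v = self._qtc_frame()
        t = v[v["hour_index"] != 0]
        with pytest.raises(ValueError, match="baseline"):
            delta_delta_qtc(v, t)


class TestPooling:
    def test_counts_conserved(self, null_result):
        pooled = null_result.pooled_onestep
        per_animal = pooled.groupby("animal_id").size().sum()
        assert per_animal == len(pooled)

    def test_four_animals_complete_hour_gives_48(self, null_result):
        counts = null_result.pooled_onestep.groupby("hour_index").size()
        assert set(counts.loc[1:6]) == {48}

    def test_dropping_one_window_gives_47(self):
        frames = {f"a{i}": pd.DataFrame({
            "window_rel": np.arange(12), "hour_index": np.ones(12, int),
            "dqtc": np.zeros(12)}) for i in range(4)}
        frames["a0"] = frames["a0"].iloc[1:]
        pooled = pool_hours(frames)
        assert len(pooled) == 47

    def test_null_delta_mean_near_zero(self, null_result):
        post = null_result.pooled_onestep.query("hour_index >= 1")
        assert abs(post["dqtc"].mean()) < 2.5
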