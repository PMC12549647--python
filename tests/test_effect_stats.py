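import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onestepqtc import (
    ClassificationConfig,
    HourlyEffect,
    classify,
    hourly_ci,
    lsd_summary,
    max_hr_change,
    peak_effect,
    slope_effect_test,
    study_lsd,
)
from onestepqtc.effect_stats import NoUsableHoursError

# one-sided 95% t quantiles from tables
T95_DF3 = 2.3534
T95_DF47 = 1.6779


def _effect(hour, mean, lsd, mode="dqtc", n=48):
    return HourlyEffect(hour_index=hour, mode=mode, n=n, mean=mean,
                        lb=mean - lsd, ub=mean + lsd, lsd=lsd)


class TestHourlyCI:
    def test_zero_variance(self):
        eff = hourly_ci([3.0, 3.0, 3.0])
        assert eff.mean == eff.lb == eff.ub == 3.0
        assert eff.lsd == 0.0

    def test_n4_sd2_matches_t_table(self):
        samples = np.array([-1.0, 1.0, -3.0, 3.0])  # mean 0
        samples = samples / samples.std(ddof=1) * 2.0  # sd exactly 2
        eff = hourly_ci(samples)
        assert eff.lsd == pytest.approx(T95_DF3, abs=2e-4)
        assert eff.lb == pytest.approx(-T95_DF3, abs=2e-4)

    def test_n48_matches_formula_oracle(self, rng):
        x = rng.normal(10.0, 3.0, 48)
        eff = hourly_ci(x)
        lsd_oracle = T95_DF47 * x.std(ddof=1) / np.sqrt(48)
        assert eff.lsd == pytest.approx(lsd_oracle, rel=1e-4)
        assert eff.mean == pytest.approx(x.mean())

    def test_single_sample_unusable(self):
        assert hourly_ci([5.0]) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_invariant(self, seed):
        x = np.random.default_rng(seed).normal(0, 5, 30)
        eff = hourly_ci(x)
        assert eff.lb <= eff.mean <= eff.ub
        assert eff.mean - eff.lb == pytest.approx(eff.ub - eff.mean)
        assert eff.lsd == pytest.approx(eff.mean - eff.lb)


class TestClassification:
    def test_lower_bound_at_5_5_is_positive(self):
        # procainamide-like hour: bounds (5.5; 8.3) at hour 1
        effects = [_effect(1, 6.9, 1.4)]
        assert effects[0].lb == pytest.approx(5.5)
        assert classify(effects) == "positive"

    def test_all_upper_bounds_below_10_is_negative(self):
        effects = [_effect(h, 1.0, 3.0) for h in range(1, 7)]
        assert classify(effects) == "negative_tqt"

    def test_cisapride_low_dose_not_positive(self):
        # bounds (2.2; 5.9): lb < 5, so no positive call
        effects = [_effect(3, 4.05, 1.85)]
        assert classify(effects) != "positive"

    def test_wide_interval_is_inconclusive(self):
        effects = [_effect(2, 4.0, 8.0)]  # lb -4, ub 12
        assert classify(effects) == "inconclusive"

    def test_no_usable_hours_raises(self):
        with pytest.raises(NoUsableHoursError):
            classify([_effect(12, 9.0, 1.0)])  # outside 1-6 window

    def test_extended_window_covers_delayed_peak(self):
        cfg = ClassificationConfig(peak_window=(1, 24))
        effects = [_effect(20, 24.0, 2.0)]
        assert classify(effects, cfg) == "positive"


class TestPeak:
    def test_monotone_rising_picks_last_hour(self):
        effects = [_effect(h, float(h), 0.5) for h in range(1, 7)]
        assert peak_effect(effects)[0] == 6

    def test_tie_picks_earliest(self):
        effects = [_effect(h, 5.0, 0.5) for h in range(1, 7)]
        assert peak_effect(effects)[0] == 1

    def test_single_nonzero_hour(self):
        effects = [_effect(h, 8.0 if h == 3 else 0.0, 0.5)
                   for h in range(1, 7)]
        hour, eff = peak_effect(effects)
        assert hour == 3 and eff.mean == 8.0


class TestMaxHrChange:
    def _dhr(self, values_by_hour):
        rows = [(f"a{i}", h, v + i * 0.0)
                for h, v in values_by_hour.items() for i in range(4)]
        return pd.DataFrame(rows, columns=["animal_id", "hour_index", "dhr"])

    def test_identical_sessions_give_zero(self):
        assert max_hr_change(self._dhr({h: 0.0 for h in range(1, 7)})) == 0.0

    def test_sign_preserved_positive(self):
        d = self._dhr({1: 2.0, 2: 20.0, 3: 5.0})
        assert max_hr_change(d) == pytest.approx(20.0)

    def test_sign_preserved_negative(self):
        d = self._dhr({1: 2.0, 2: -15.0, 3: 5.0})
        assert max_hr_change(d) == pytest.approx(-15.0)


class TestSlopeEffectTest:
    def _pairs(self, dbeta, n_animals=4, base=-0.5, hours=(1, 2)):
        rows = []
        for h in hours:
            for i in range(n_animals):
                rows.append((f"a{i}", h, base, base + dbeta[i]))
        return pd.DataFrame(rows, columns=["animal_id", "hour_index",
                                           "beta_vehicle", "beta_treated"])

    def test_identical_slopes(self):
        out = slope_effect_test(self._pairs([0.0] * 4))
        assert np.all(out["dbeta_mean"] == 0.0)
        assert np.all(out["p"] == 1.0)
        assert np.all(out["degenerate"])

    def test_constant_shift_zero_variance_degenerate(self):
        out = slope_effect_test(self._pairs([-0.3] * 4))
        assert np.all(out["p"] == 0.0)
        assert np.all(out["degenerate"])
        assert np.allclose(out["dbeta_mean"], -0.3)

    def test_power_matches_noncentral_t_oracle(self):
        """Rejection rate of a -0.2 shift with sd 0.05, n=4 paired test."""
        rng = np.random.default_rng(77)
        n_rep, alpha, n = 300, 0.05, 4
        rejections = 0
        for _ in range(n_rep):
            d = rng.normal(-0.2, 0.05, n)
            out = slope_effect_test(self._pairs(d, hours=(1,)))
            rejections += float(out["p"].iloc[0]) <= alpha
        ncp = 0.2 / (0.05 / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) \
            + stats.nct.cdf(-tcrit, n - 1, ncp)
        assert rejections / n_rep == pytest.approx(power, abs=0.05)

    def test_too_few_pairs_skipped(self):
        out = slope_effect_test(self._pairs([0.1], n_animals=1))
        assert out.empty


class TestLsdSummary:
    def test_single_study_median_is_itself(self):
        df = lsd_summary({"s1": {"onestep": 2.0, "linqthr": 6.0}})
        assert df.loc["median", "onestep"] == 2.0

    def test_median_of_three(self):
        per = {f"s{i}": {"onestep": v} for i, v in enumerate([1.0, 2.0, 9.0])}
        assert lsd_summary(per).loc["median", "onestep"] == 2.0

    def test_study_lsd_reductions(self):
        effects = [_effect(h, 0.0, lsd) for h, lsd in
                   zip(range(1, 6), [1.0, 2.0, 3.0, 4.0, 9.0])]
        assert study_lsd(effects) == 3.0
        assert study_lsd(effects, reduce="max") == 9.0
        assert study_lsd(effects, reduce="mean") == pytest.approx(3.8)
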