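"""Median split, Kaplan-Meier, and the Mantel-Cox log-rank statistic."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from il6_episcreen.data import Endpoint, SurvivalRecord
from il6_episcreen.exceptions import DegenerateDataError, InsufficientDataError
from il6_episcreen.survival import (
    km_estimate,
    logrank_test,
    median_split,
    survival_screen,
)


def oe_oracle(times_low, events_low, times_high, events_high):
    """Independent O/E/V accumulation over distinct event times, written as
    plain hypergeometric bookkeeping for the test only."""
    records = [(t, e, 0) for t, e in zip(times_low, events_low)]
    records += [(t, e, 1) for t, e in zip(times_high, events_high)]
    event_times = sorted({t for t, e, _ in records if e == 1})
    O = E = V = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in records if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 1)
        d = sum(1 for tt, ee, _ in records if tt == t and ee == 1)
        d1 = sum(1 for tt, ee, g in records if tt == t and ee == 1 and g == 1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return chi2, O - E


class TestMedianSplit:
    def test_even_split(self):
        low, high = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert low == {"a", "b"}
        assert high == {"c", "d"}

    def test_ties_go_low(self):
        low, high = median_split(pd.Series([1, 2, 2, 4], index=list("abcd")))
        assert low == {"a", "b", "c"}
        assert high == {"d"}

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            median_split(pd.Series([5, 5, 5, 5], index=list("abcd")))

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            median_split(pd.Series([1, 2, 3], index=list("abc")))

    def test_heavy_upper_ties_still_split(self):
        low, high = median_split(pd.Series([1, 2, 2, 2], index=list("abcd")))
        assert low and high and low | high == set("abcd")


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival(0.5) == pytest.approx(1.0)
        assert curve.survival(1.0) == pytest.approx(2 / 3)
        assert curve.survival(2.0) == pytest.approx(1 / 3)
        assert curve.survival(3.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([5.0, 8.0, 9.0], [0, 0, 0])
        assert curve.survival(9.0) == pytest.approx(1.0)

    def test_mixed_toy_matches_hand_product_limit(self):
        # events at 1,3,4,6,8; censored at 2,5,7:
        # S = 7/8, 35/48, 7/12, 7/18, 0 at successive event times
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 0, 1, 1, 0, 1, 0, 1]
        curve = km_estimate(times, events)
        assert curve.survival(1) == pytest.approx(7 / 8)
        assert curve.survival(3) == pytest.approx(35 / 48)
        assert curve.survival(4) == pytest.approx(7 / 12)
        assert curve.survival(6) == pytest.approx(7 / 18)
        assert curve.survival(8) == pytest.approx(0.0)

    def test_monotone_non_increasing(self, rng):
        times = rng.exponential(100, 50)
        events = rng.integers(0, 2, 50)
        curve = km_estimate(times, events)
        assert (np.diff(curve.step_values) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            km_estimate([], [])


def frame(times, events, prefix):
    return pd.DataFrame(
        {"time": times, "event": events},
        index=[f"{prefix}{i}" for i in range(len(times))],
    )


class TestLogRank:
    def test_identical_groups_null(self):
        g = frame([1, 2, 3, 4], [1, 1, 0, 1], "a")
        chi2, p, _ = logrank_test(g, g.set_index(g.index + "_b"))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_toy_dataset_matches_oe_oracle(self):
        tl, el = [5, 8, 12, 20], [1, 1, 0, 1]
        th, eh = [3, 4, 7, 9], [1, 1, 1, 0]
        chi2, p, direction = logrank_test(frame(tl, el, "l"), frame(th, eh, "h"))
        expected_chi2, oe = oe_oracle(tl, el, th, eh)
        assert chi2 == pytest.approx(expected_chi2, abs=1e-9)
        assert direction == ("unfavorable" if oe > 0 else "favorable")

    def test_matches_lifelines(self, rng):
        tl = rng.exponential(100, 40)
        th = rng.exponential(60, 40)
        el = rng.integers(0, 2, 40)
        eh = rng.integers(0, 2, 40)
        if el.sum() + eh.sum() == 0:
            el[0] = 1
        chi2, p, _ = logrank_test(frame(tl, el, "l"), frame(th, eh, "h"))
        ref = lifelines_logrank(tl, th, event_observed_A=el, event_observed_B=eh)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetry_swapping_groups_flips_direction(self, rng):
        a = frame(rng.exponential(100, 30), np.ones(30, int), "a")
        b = frame(rng.exponential(40, 30), np.ones(30, int), "b")
        chi_ab, _, dir_ab = logrank_test(a, b)
        chi_ba, _, dir_ba = logrank_test(b, a)
        assert chi_ab == pytest.approx(chi_ba)
        assert {dir_ab, dir_ba} == {"favorable", "unfavorable"}

    def test_shifted_times_detected_with_shift_sign(self):
        low = frame(np.arange(1, 21) + 50.0, np.ones(20, int), "l")
        high = frame(np.arange(1, 21), np.ones(20, int), "h")
        chi2, _, direction = logrank_test(low, high)
        assert chi2 > 0
        assert direction == "unfavorable"  # high group dies earlier

    def test_zero_events_undefined(self):
        with pytest.raises(DegenerateDataError):
            logrank_test(frame([1, 2], [0, 0], "l"), frame([3, 4], [0, 0], "h"))


class TestSurvivalScreen:
    def make_records(self, rng, n=60, hr=3.0):
        values = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        high = values > values.median()
        hazard = 0.01 * np.where(high, hr, 1.0)
        times = rng.exponential(1 / hazard)
        censor = rng.uniform(0, 300, n)
        records = [
            SurvivalRecord(f"S{i}", Endpoint.OS, float(max(min(times[i], censor[i]), 1e-9)),
                           int(times[i] <= censor[i]))
            for i in range(n)
        ]
        return values, records

    def test_planted_hazard_called_unfavorable(self, rng):
        values, records = self.make_records(rng, n=200, hr=4.0)
        result = survival_screen(values, records, "OS", stratifier_id="G",
                                 cohort="C01")
        assert result.direction == "unfavorable"
        assert result.significant

    def test_protective_effect_called_favorable(self, rng):
        values, records = self.make_records(rng, n=200, hr=0.25)
        result = survival_screen(values, records, "OS")
        assert result.direction == "favorable"
        assert result.significant

    def test_non_overlapping_samples_error(self, rng):
        values, records = self.make_records(rng)
        values.index = "X" + values.index
        with pytest.raises(InsufficientDataError):
            survival_screen(values, records, "OS")

    def test_mean_split_option_runs(self, rng):
        values, records = self.make_records(rng)
        result = survival_screen(values, records, "OS", split="mean")
        assert result.n_high + result.n_low == len(values)
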