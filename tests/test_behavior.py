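import numpy as np
import pandas as pd
import pytest
from mpmath import erfinv, mpf, sqrt as mpsqrt

from marmoephys.behavior import (
    FIG8B_CONTRASTS,
    bootstrap_sdt,
    bootstrap_sdt_contrast,
    classify_trial_outcomes,
    clopper_pearson,
    condition_rates,
    corrected_false_alarm_rate,
    detect_saccades,
    dprime_criterion,
    pairwise_rate_tests,
)
from marmoephys.core import EyeTrace, TrialTable, seeded_rng
from marmoephys.core.types import TRIAL_COLUMNS, ValidationError
from marmoephys.synth import EyeSimParams, SaccadePlan, simulate_eye_trace


def make_trials(rows):
    return TrialTable(pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)))


def go_trial(tid, cond="high", response=None, onset=0.35):
    target = onset if cond in ("high", "high+opto", "low", "low+opto") \
        else np.nan
    laser = onset if cond in ("high+opto", "low+opto", "opto_only", "sham") \
        else np.nan
    return {"trial_id": tid, "condition": cond, "fixation_on": 0.0,
            "background_on": 0.12, "target_on": target, "laser_on": laser,
            "response_time": np.nan if response is None else onset + response,
            "outcome": ""}


class TestDetectSaccades:
    def test_constant_trace_none(self):
        t = np.arange(1000) / 1000.0
        eye = EyeTrace(t=t, x=np.ones(1000), y=np.ones(1000), rate=1000.0)
        assert detect_saccades(eye) == []

    def test_simulated_8deg(self):
        eye, gt = simulate_eye_trace([SaccadePlan(0.5, 8.0, 30.0)], 1.2,
                                     EyeSimParams(), seed=0)
        events = detect_saccades(eye)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.onset - gt.onsets[0]) <= 0.003
        assert ev.amplitude == pytest.approx(8.0, abs=0.2)
        assert abs((ev.direction - 30.0 + 180) % 360 - 180) < 10.0

    def test_two_saccades_100ms_apart(self):
        plans = [SaccadePlan(0.4, 6.0, 0.0), SaccadePlan(0.5, 6.0, 180.0)]
        eye, _ = simulate_eye_trace(plans, 1.0, EyeSimParams(), seed=1)
        events = detect_saccades(eye)
        assert len(events) == 2

    def test_short_trace_rejected(self):
        t = np.arange(20) / 1000.0
        eye = EyeTrace(t=t, x=np.zeros(20), y=np.zeros(20), rate=1000.0)
        with pytest.raises(ValidationError):
            detect_saccades(eye)

    def test_saccade_at_end_flagged(self):
        n = 600
        t = np.arange(n) / 1000.0
        x = np.zeros(n)
        x[-12:] = np.linspace(0.0, 6.0, 12)  # fast ramp into the trace end
        eye = EyeTrace(t=t, x=x, y=np.zeros(n), rate=1000.0)
        events = detect_saccades(eye)
        assert len(events) == 1
        assert not events[0].endpoint_defined

    def test_blink_not_a_saccade(self):
        eye, _ = simulate_eye_trace(
            [], 1.0, EyeSimParams(jitter_sigma=0.0, blink_times=(0.4,)),
            seed=0)
        assert detect_saccades(eye) == []


class TestOutcomes:
    def test_hit(self):
        scored = classify_trial_outcomes(make_trials([go_trial(0, response=0.2)]))
        assert scored.df["outcome"][0] == "hit"

    def test_early(self):
        scored = classify_trial_outcomes(make_trials([go_trial(0, response=0.03)]))
        assert scored.df["outcome"][0] == "early"

    def test_miss(self):
        scored = classify_trial_outcomes(make_trials([go_trial(0)]))
        assert scored.df["outcome"][0] == "miss"

    def test_late_response_is_miss(self):
        scored = classify_trial_outcomes(make_trials([go_trial(0, response=0.6)]))
        assert scored.df["outcome"][0] == "miss"

    def test_catch_correct_rejection(self):
        row = {"trial_id": 0, "condition": "catch", "fixation_on": 0.0,
               "background_on": 0.12, "target_on": np.nan,
               "laser_on": np.nan, "response_time": np.nan, "outcome": ""}
        scored = classify_trial_outcomes(make_trials([row]))
        assert scored.df["outcome"][0] == "correct_rejection"

    def test_catch_false_alarm(self):
        row = {"trial_id": 0, "condition": "catch", "fixation_on": 0.0,
               "background_on": 0.12, "target_on": np.nan,
               "laser_on": np.nan, "response_time": 0.5, "outcome": ""}
        scored = classify_trial_outcomes(make_trials([row]))
        assert scored.df["outcome"][0] == "false_alarm"

    def test_opto_only_uses_laser_onset(self):
        scored = classify_trial_outcomes(
            make_trials([go_trial(0, cond="opto_only", response=0.2)]))
        assert scored.df["outcome"][0] == "hit"

    def test_missing_reference_onset(self):
        row = go_trial(0)
        row["target_on"] = np.nan
        with pytest.raises(ValidationError, match="reference"):
            classify_trial_outcomes(make_trials([row]))

    def test_partition(self, fig8_session):
        scored = classify_trial_outcomes(fig8_session)
        assert (scored.df["outcome"] != "").all()

    def test_saccade_driven_scoring(self):
        trials = make_trials([go_trial(0, response=None)])
        eye, _ = simulate_eye_trace([SaccadePlan(0.55, 8.0, 0.0)], 1.2,
                                    EyeSimParams(), seed=0)
        saccades = detect_saccades(eye)
        scored = classify_trial_outcomes(trials, saccades)
        assert scored.df["outcome"][0] == "hit"  # 0.55 - 0.35 = 200 ms


class TestConditionRates:
    def test_zero_responders(self):
        rows = [go_trial(i) for i in range(10)]
        scored = classify_trial_outcomes(make_trials(rows))
        rates = condition_rates(scored)
        assert rates.rates["high"] == 0.0
        assert rates.ci["high"][0] == 0.0

    def test_ci_contains_rate(self, fig8_session):
        rates = condition_rates(classify_trial_outcomes(fig8_session))
        for c in rates.conditions:
            lo, hi = rates.ci[c]
            assert lo <= rates.rates[c] <= hi

    def test_clopper_pearson_known_value(self):
        # 8/10: exact CP interval, independently verifiable
        lo, hi = clopper_pearson(8, 10)
        assert lo == pytest.approx(0.4439, abs=2e-4)
        assert hi == pytest.approx(0.9748, abs=2e-4)


class TestCorrectedFA:
    def test_all_inside_windows(self):
        # every catch saccade inside every go window -> corrected = raw
        fa = np.full(20, 0.4)
        go = np.full(50, 0.2)  # window [0.25, 0.7)
        out = corrected_false_alarm_rate(fa, 40, go, reps=200, seed=0)
        assert out.rate == pytest.approx(0.5, abs=0.001)
        assert out.rate == pytest.approx(out.raw_rate, abs=0.001)

    def test_all_outside_windows(self):
        fa = np.full(20, 0.1)
        go = np.full(50, 0.2)
        out = corrected_false_alarm_rate(fa, 40, go, reps=200, seed=0)
        assert out.rate == 0.0

    def test_corrected_never_exceeds_raw(self):
        rng = seeded_rng(1, "fa")
        fa = rng.uniform(0.0, 0.8, 30)
        go = rng.uniform(0.15, 0.32, 100)
        out = corrected_false_alarm_rate(fa, 80, go, reps=300, seed=2)
        assert out.rate <= out.raw_rate + 1e-12

    def test_default_n_pairs(self):
        out = corrected_false_alarm_rate(np.array([0.3]), 10,
                                         np.full(700, 0.2), reps=10, seed=0)
        assert out.n_pairs == 467  # round(700 * 0.4/0.6)

    def test_poisson_hazard_closed_form(self):
        # catch saccades ~ Exp(lam) truncated at 0.8; go onsets ~ U(0.15,0.32)
        lam = 1.5
        rng = seeded_rng(3, "fa-hazard")
        rates = []
        for _ in range(8):
            draws = rng.exponential(1.0 / lam, 400)
            fa = draws[draws < 0.8]
            go = rng.uniform(0.15, 0.32, 600)
            out = corrected_false_alarm_rate(fa, 400, go, reps=300,
                                             seed=int(rng.integers(1e6)))
            rates.append(out.rate)
        # oracle: E_T[exp(-lam(T+0.05)) - exp(-lam*min(T+0.5, 0.8))]
        T = np.linspace(0.15, 0.32, 10001)
        expected = np.mean(np.exp(-lam * (T + 0.05))
                           - np.exp(-lam * np.minimum(T + 0.5, 0.8)))
        assert np.mean(rates) == pytest.approx(
            expected, abs=2 * np.std(rates) / np.sqrt(len(rates)) + 0.01)

    def test_no_go_trials_rejected(self):
        with pytest.raises(ValidationError):
            corrected_false_alarm_rate(np.array([0.3]), 10, np.array([]))

    def test_fa_only_pool(self):
        fa = np.full(20, 0.4)
        go = np.full(50, 0.2)
        out = corrected_false_alarm_rate(fa, 40, go, reps=100, seed=0,
                                         catch_pool="fa_only")
        assert out.rate == pytest.approx(0.5, abs=0.01)


class TestPairwiseTests:
    def test_identical_proportions(self):
        tables = {c: (50, 100) for c in
                  ("high", "high+opto", "low", "low+opto", "opto_only",
                   "sham", "catch")}
        out = pairwise_rate_tests(tables)
        assert (out["p_raw"] > 0.9).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_adjusted_monotone_and_geq_raw(self, fig8_session):
        rates = condition_rates(classify_trial_outcomes(fig8_session))
        tables = {c: (rates.responders[c], rates.totals[c])
                  for c in rates.conditions}
        out = pairwise_rate_tests(tables)
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        srt = out.sort_values("p_raw")
        assert srt["p_adj"].is_monotonic_increasing

    def test_low_count_warning(self):
        tables = {"high": (1, 3), "low": (0, 3)}
        with pytest.warns(UserWarning, match="expected cell"):
            out = pairwise_rate_tests(tables, family=(("high", "low"),))
        assert np.isfinite(out["p_raw"][0])


class TestDPrime:
    def test_textbook_point(self):
        d, c = dprime_criterion(0.8413, 0.1587)
        assert d == pytest.approx(2.0, abs=1e-3)
        assert c == pytest.approx(0.0, abs=1e-3)

    def test_equal_rates_zero_d(self):
        for p in (0.1, 0.5, 0.9):
            d, c = dprime_criterion(p, p)
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_swap_symmetries(self):
        h, f = 0.82, 0.31
        d1, c1 = dprime_criterion(h, f)
        d2, c2 = dprime_criterion(f, h)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_boundary_rejected_with_advice(self):
        with pytest.raises(ValueError, match="correction"):
            dprime_criterion(1.0, 0.2)

    def test_boundary_correction_flag(self):
        d, c = dprime_criterion(1.0, 0.2, correction_n=(100, 100))
        d_ref, _ = dprime_criterion(1.0 - 0.005, 0.2)
        assert d == pytest.approx(d_ref, abs=1e-12)

    def test_matches_inverse_normal_oracle(self):
        # independent high-precision oracle: Z(p) = sqrt(2) erfinv(2p - 1)
        grid = np.linspace(0.01, 0.99, 99)
        for h in grid[::7]:
            for f in grid[::7]:
                d, c = dprime_criterion(float(h), float(f))
                zh = float(mpsqrt(2) * erfinv(2 * mpf(repr(float(h))) - 1))
                zf = float(mpsqrt(2) * erfinv(2 * mpf(repr(float(f))) - 1))
                assert d == pytest.approx(zh - zf, abs=1e-9)
                assert c == pytest.approx(-0.5 * (zh + zf), abs=1e-9)


class TestBootstrapSDT:
    def test_ci_contains_point_estimate(self):
        res = bootstrap_sdt(66, 52, 156, 311, b=2000, seed=0)
        assert res.dprime_ci[0] <= res.dprime <= res.dprime_ci[1]
        assert res.criterion_ci[0] <= res.criterion <= res.criterion_ci[1]

    def test_self_contrast_null(self):
        counts = (66, 52, 156, 311)
        con = bootstrap_sdt_contrast(counts, counts, b=4000, seed=1)
        assert 0.3 <= con.p_dprime <= 0.7
        assert abs(con.delta_dprime) < 1e-12

    def test_large_separation_hits_floor(self):
        con = bootstrap_sdt_contrast((50, 50, 20, 80), (95, 5, 20, 80),
                                     b=10000, seed=2)
        assert con.p_dprime == pytest.approx(1e-4)

    def test_ci_width_scales_inverse_sqrt_n(self):
        res1 = bootstrap_sdt(60, 40, 30, 70, b=4000, seed=3)
        res4 = bootstrap_sdt(240, 160, 120, 280, b=4000, seed=3)
        w1 = res1.dprime_ci[1] - res1.dprime_ci[0]
        w4 = res4.dprime_ci[1] - res4.dprime_ci[0]
        assert w1 / w4 == pytest.approx(2.0, rel=0.2)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sdt(0, 10, 5, 5)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sdt(5, 5, 5, 5, b=50)

    def test_literal_method_self_contrast(self):
        counts = (66, 52, 156, 311)
        con = bootstrap_sdt_contrast(counts, counts, b=4000, seed=4,
                                     method="literal")
        assert 0.3 <= con.p_dprime <= 0.7

    def test_reproducible(self):
        a = bootstrap_sdt(66, 52, 156, 311, b=1000, seed=7)
        b2 = bootstrap_sdt(66, 52, 156, 311, b=1000, seed=7)
        assert a.dprime_ci == b2.dprime_ci
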