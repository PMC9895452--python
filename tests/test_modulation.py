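import numpy as np
import pytest

from marmoephys.core import SpikeCluster, seeded_rng
from marmoephys.core.types import ValidationError
from marmoephys.modulation import (
    autocorrelogram,
    classify_mua_modulation,
    classify_sua_modulation,
    compute_psth,
    firing_rate_stability,
    fit_orientation_tuning,
    zscore_to_baseline,
)
from marmoephys.preprocess import TrialTensor


def make_tensor(values, rate=1000.0, window=(-0.25, 0.65)):
    return TrialTensor(values, rate, window)


def null_tensor(rng, n_trials=20, n_ch=1, window=(-0.25, 0.65), rate=1000.0):
    n = int(round((window[1] - window[0]) * rate))
    return make_tensor(rng.normal(10.0, 1.0, size=(n_trials, n_ch, n)),
                       rate, window)


def step_tensor(rng, amplitude, n_trials=20, window=(-0.25, 0.65),
                rate=1000.0):
    n = int(round((window[1] - window[0]) * rate))
    vals = rng.normal(10.0, 1.0, size=(n_trials, 1, n))
    onset = int(round(-window[0] * rate))
    vals[:, :, onset:] += amplitude
    return make_tensor(vals, rate, window)


class TestZScore:
    def test_step_of_5_sigma(self):
        rng = seeded_rng(0, "z")
        tensor = step_tensor(rng, 5.0 / np.sqrt(20))
        z = zscore_to_baseline(tensor, (-0.25, 0.0))
        stim = z[0, 250:]
        # trial-averaged sigma is sigma/sqrt(n_trials), so the step is ~5 sd
        assert np.median(stim) == pytest.approx(5.0, abs=1.0)

    def test_small_z_under_null(self):
        rng = seeded_rng(1, "z")
        z = zscore_to_baseline(null_tensor(rng), (-0.25, 0.0))
        assert np.abs(np.mean(z)) < 1.0

    def test_affine_invariance(self):
        rng = seeded_rng(2, "z")
        tensor = step_tensor(rng, 3.0)
        z1 = zscore_to_baseline(tensor, (-0.25, 0.0))
        scaled = make_tensor(tensor.values * 7.0 + 100.0, tensor.rate,
                             tensor.window)
        z2 = zscore_to_baseline(scaled, (-0.25, 0.0))
        np.testing.assert_allclose(z1, z2, rtol=1e-9, atol=1e-9)

    def test_zero_variance_error(self):
        tensor = make_tensor(np.ones((5, 2, 900)))
        with pytest.raises(ValidationError, match="channels"):
            zscore_to_baseline(tensor, (-0.25, 0.0))


class TestMUAClassifier:
    def test_null_not_modulated(self):
        rng = seeded_rng(3, "mua")
        res = classify_mua_modulation(null_tensor(rng), (-0.25, 0.0),
                                      (0.0, 0.65))
        assert not res.modulated[0]

    def test_strong_step_modulated(self):
        rng = seeded_rng(4, "mua")
        tensor = step_tensor(rng, 10.0)
        res = classify_mua_modulation(tensor, (-0.25, 0.0), (0.0, 0.65))
        assert res.modulated[0]
        assert res.max_abs_z[0] > 3.0
        assert res.p_value[0] < 0.05

    def test_overlapping_windows_rejected(self):
        rng = seeded_rng(5, "mua")
        with pytest.raises(ValidationError, match="disjoint"):
            classify_mua_modulation(null_tensor(rng), (-0.25, 0.1),
                                    (0.0, 0.65))

    def test_channel_order_invariance(self):
        rng = seeded_rng(6, "mua")
        tensor = null_tensor(rng, n_ch=4)
        tensor.values[:, 2, 250:] += 8.0
        res = classify_mua_modulation(tensor, (-0.25, 0.0), (0.0, 0.65))
        perm = [3, 2, 1, 0]
        permuted = make_tensor(tensor.values[:, perm, :], tensor.rate,
                               tensor.window)
        res_p = classify_mua_modulation(permuted, (-0.25, 0.0), (0.0, 0.65))
        np.testing.assert_array_equal(res.modulated[perm], res_p.modulated)

    def test_pooled_mode_runs(self):
        rng = seeded_rng(7, "mua")
        tensor = step_tensor(rng, 10.0)
        res = classify_mua_modulation(tensor, (-0.25, 0.0), (0.0, 0.65),
                                      samples="pooled")
        assert res.modulated[0]


class TestSUAClassifier:
    @staticmethod
    def poisson_unit(rate_stim, rate_ctrl, n_trials, rng, window=0.25):
        stim_ev = np.arange(n_trials) * 2.0 + 1.0
        ctrl_ev = np.arange(n_trials) * 2.0 + 1.0 + 2.0 * n_trials
        times = []
        for ev, r in [(stim_ev, rate_stim), (ctrl_ev, rate_ctrl)]:
            for e in ev:
                n = rng.poisson(r * (window + 0.25))
                times.append(rng.uniform(e - 0.25, e + window, n))
        st = np.sort(np.concatenate(times))
        return SpikeCluster(0, st), stim_ev, ctrl_ev

    def test_rate_ratio_5x_modulated(self):
        rng = seeded_rng(8, "sua")
        unit, stim_ev, ctrl_ev = self.poisson_unit(50.0, 10.0, 30, rng)
        res = classify_sua_modulation(unit, stim_ev, ctrl_ev,
                                      (-0.25, 0.0), (0.0, 0.25))
        assert res.modulated[0]

    def test_zero_spikes_not_modulated(self):
        unit = SpikeCluster(0, np.array([]))
        res = classify_sua_modulation(unit, np.array([1.0]), np.array([3.0]),
                                      (-0.25, 0.0), (0.0, 0.25))
        assert not res.modulated[0]

    def test_type_i_calibration(self):
        # equal rates in both groups: modulated fraction should be ~alpha
        # or below (the conjunction with the z criterion is conservative)
        rng = seeded_rng(9, "sua-null")
        n_sig = 0
        n_rep = 60
        for _ in range(n_rep):
            unit, stim_ev, ctrl_ev = self.poisson_unit(20.0, 20.0, 20, rng)
            res = classify_sua_modulation(unit, stim_ev, ctrl_ev,
                                          (-0.25, 0.0), (0.0, 0.25))
            n_sig += int(res.modulated[0])
        assert n_sig / n_rep <= 0.1

    def test_empty_group_rejected(self):
        unit = SpikeCluster(0, np.array([1.0, 2.0]))
        with pytest.raises(ValidationError, match="nonempty"):
            classify_sua_modulation(unit, np.array([]), np.array([1.0]),
                                    (-0.25, 0.0), (0.0, 0.25))


class TestPSTH:
    def test_poisson_rate_recovered(self):
        rng = seeded_rng(10, "psth")
        r = 40.0
        events = np.arange(50) * 2.0 + 0.5
        st = np.sort(rng.uniform(0.0, 100.0, int(r * 100)))
        t, rate, sem = compute_psth(st, events, (-0.25, 0.5), sigma_s=0.01)
        core = slice(50, -50)
        mean_err = abs(rate[core].mean() - r)
        assert mean_err < 3.0 * sem[core].mean() + 1.0

    def test_no_spikes_zero(self):
        t, rate, sem = compute_psth(np.array([]), np.array([1.0]),
                                    (-0.1, 0.1))
        np.testing.assert_allclose(rate, 0.0)

    def test_count_preserved(self):
        # unit-integral kernel: total smoothed count within 1%
        rng = seeded_rng(11, "psth2")
        st = np.sort(rng.uniform(0.4, 0.6, 200))
        t, rate, _ = compute_psth(st, np.array([0.5]), (-0.4, 0.4),
                                  sigma_s=0.005)
        total = rate.sum() * 0.001
        assert total == pytest.approx(200.0, rel=0.01)


class TestACG:
    def test_regular_train_peaks_at_period(self):
        st = np.arange(0.0, 10.0, 0.01)  # 100 Hz regular
        lags, acg = autocorrelogram(st)
        peak_lags = lags[acg == 1.0]
        assert np.any(np.abs(peak_lags - 0.01) < 0.0005)
        assert np.any(np.abs(peak_lags + 0.01) < 0.0005)

    def test_symmetric(self):
        rng = seeded_rng(12, "acg")
        st = np.sort(rng.uniform(0.0, 5.0, 500))
        lags, acg = autocorrelogram(st)
        np.testing.assert_array_equal(acg, acg[::-1])

    def test_zero_lag_removed(self):
        st = np.arange(0.0, 10.0, 0.01)
        lags, acg = autocorrelogram(st)
        assert acg[np.argmin(np.abs(lags))] == 0.0

    def test_poisson_flat(self):
        rng = seeded_rng(13, "acg-poisson")
        st = np.sort(rng.uniform(0.0, 1000.0, 100_000))
        lags, acg = autocorrelogram(st)
        nz = acg[acg > 0]
        assert nz.max() / nz.min() < 1.5

    def test_too_few_spikes(self):
        with pytest.raises(ValidationError):
            autocorrelogram(np.array([1.0]))


class TestTuning:
    ORIENTATIONS = np.arange(22.5, 181.0, 22.5)

    def test_flat_rates(self):
        fit = fit_orientation_tuning(self.ORIENTATIONS,
                                     np.full(8, 12.0))
        assert fit.kappa == 0.0
        assert fit.amplitude == 0.0

    def test_parameter_recovery(self):
        rng = seeded_rng(14, "tuning")
        b, a, kappa, pref = 5.0, 20.0, 2.0, 45.0
        th = np.deg2rad(self.ORIENTATIONS)
        rates = b + a * np.exp(kappa * (np.cos(2 * (th - np.deg2rad(pref)))
                                        - 1.0))
        rates = rates + rng.normal(0.0, 0.3, rates.size)
        fit = fit_orientation_tuning(self.ORIENTATIONS, rates)
        err = abs((fit.pref_orientation - pref + 90.0) % 180.0 - 90.0)
        assert err < 5.0

    def test_pref_in_range(self):
        rng = seeded_rng(15, "tuning2")
        rates = rng.uniform(5.0, 20.0, 8)
        fit = fit_orientation_tuning(self.ORIENTATIONS, rates)
        assert 0.0 <= fit.pref_orientation < 180.0
        assert fit.kappa >= 0.0

    def test_too_few_orientations(self):
        with pytest.raises(ValidationError):
            fit_orientation_tuning(np.array([0.0, 45.0, 90.0]),
                                   np.array([1.0, 2.0, 3.0]))


class TestStability:
    def test_homogeneous_flat(self):
        rng = seeded_rng(16, "stab")
        st = np.sort(rng.uniform(0.0, 100.0, 2000))  # 20 sp/s
        t, rate = firing_rate_stability(st, 100.0)
        assert np.all(np.abs(rate - 20.0) / 20.0 < 0.35)
        assert abs(rate.mean() - 20.0) / 20.0 < 0.1

    def test_output_span(self):
        st = np.linspace(0.0, 100.0, 500)
        t, rate = firing_rate_stability(st, 100.0)
        assert t.min() >= 5.0
        assert t.max() <= 95.0

    def test_empty_train_zero(self):
        t, rate = firing_rate_stability(np.array([]), 50.0)
        np.testing.assert_allclose(rate, 0.0)

    def test_short_session_rejected(self):
        with pytest.raises(ValidationError):
            firing_rate_stability(np.array([1.0, 2.0]), 10.0)
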