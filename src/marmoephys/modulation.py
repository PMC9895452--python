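"""Neural modulation statistics.

A channel (MUA) counts as modulated when the trial-averaged response exceeds
3 baseline standard deviations in absolute z AND a two-sided two-sample
Kolmogorov-Smirnov test between baseline-window and stimulus-window values
rejects at alpha = 0.05. Single units use the analogous conjunction with a
two-sided Wilcoxon rank-sum test on per-trial spike counts between the
stimulated and control trial groups.

Also provides Gaussian-smoothed PSTHs, normalized autocorrelograms at
0.33 ms resolution, von Mises orientation-tuning fits and session-long
firing-rate stability traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core.config import AnalysisConfig
from .core.types import SpikeCluster, ValidationError
from .preprocess import TrialTensor

__all__ = [
    "ModulationResult",
    "TuningFit",
    "zscore_to_baseline",
    "classify_mua_modulation",
    "classify_sua_modulation",
    "compute_psth",
    "autocorrelogram",
    "fit_orientation_tuning",
    "firing_rate_stability",
]


@dataclass
class ModulationResult:
    z_profile: np.ndarray  # z vs time per channel (channels, time) or (time,)
    max_abs_z: np.ndarray  # per channel
    p_value: np.ndarray  # per channel
    modulated: np.ndarray  # bool per channel
    baseline_window: tuple[float, float] = (0.0, 0.0)
    stim_window: tuple[float, float] = (0.0, 0.0)


@dataclass
class TuningFit:
    orientations: np.ndarray  # degrees
    means: np.ndarray
    sems: np.ndarray
    baseline: float
    amplitude: float
    kappa: float
    pref_orientation: float  # degrees, in [0, 180)
    residual: float

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        pref = np.deg2rad(self.pref_orientation)
        return self.baseline + self.amplitude * np.exp(
            self.kappa * (np.cos(2.0 * (th - pref)) - 1.0)
        )


def _window_slices(tensor: TrialTensor,
                   baseline: tuple[float, float],
                   stim: tuple[float, float]) -> tuple[slice, slice]:
    if max(baseline[0], stim[0]) < min(baseline[1], stim[1]):
        raise ValidationError("baseline and stimulus windows must be disjoint")
    return tensor.window_slice(baseline), tensor.window_slice(stim)


def zscore_to_baseline(tensor: TrialTensor,
                       baseline: tuple[float, float]) -> np.ndarray:
    """z-score the trial-averaged trace against its own baseline samples.

    Returns a ``(channels, time)`` z profile. A channel with zero baseline
    variance is an error (it carries no noise estimate to scale by).
    """
    sl = tensor.window_slice(baseline)
    avg = tensor.values.mean(axis=0)  # (channels, time)
    mu = avg[:, sl].mean(axis=1, keepdims=True)
    sd = avg[:, sl].std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValidationError(f"zero baseline variance on channels {zero.tolist()}")
    return (avg - mu) / sd


def classify_mua_modulation(tensor: TrialTensor,
                            baseline: tuple[float, float],
                            stim: tuple[float, float],
                            config: AnalysisConfig | None = None,
                            samples: str = "trial_average") -> ModulationResult:
    """Joint |z| > 3 and KS (p < 0.05) modulation test per channel.

    ``samples`` selects what enters the KS test: time samples of the
    trial-averaged trace (default) or all per-trial samples pooled
    (``"pooled"``).
    """
    cfg = config or AnalysisConfig()
    sl_base, sl_stim = _window_slices(tensor, baseline, stim)
    for name, sl in (("baseline", sl_base), ("stimulus", sl_stim)):
        if sl.stop - sl.start < 5:
            raise ValidationError(f"{name} window has fewer than 5 samples")
    z = zscore_to_baseline(tensor, baseline)
    max_abs_z = np.abs(z[:, sl_stim]).max(axis=1)

    avg = tensor.values.mean(axis=0)
    n_ch = avg.shape[0]
    p = np.empty(n_ch)
    for ch in range(n_ch):
        if samples == "trial_average":
            a, b = avg[ch, sl_base], avg[ch, sl_stim]
        elif samples == "pooled":
            a = tensor.values[:, ch, sl_base].ravel()
            b = tensor.values[:, ch, sl_stim].ravel()
        else:
            raise ValueError(f"unknown samples mode {samples!r}")
        p[ch] = stats.ks_2samp(a, b, method="asymp").pvalue
    modulated = (max_abs_z > cfg.z_threshold) & (p < cfg.ks_alpha)
    return ModulationResult(z, max_abs_z, p, modulated, baseline, stim)


def classify_sua_modulation(unit: SpikeCluster,
                            stim_events: np.ndarray,
                            control_events: np.ndarray,
                            baseline: tuple[float, float],
                            stim: tuple[float, float],
                            config: AnalysisConfig | None = None,
                            rate_bin_s: float = 0.001) -> ModulationResult:
    """Single-unit modulation: rank-sum on per-trial stimulus-window counts
    (stimulated vs control trials) AND trial-averaged rate exceeding 3
    baseline STDs. A unit without spikes is simply not modulated.
    """
    cfg = config or AnalysisConfig()
    stim_events = np.asarray(stim_events, float)
    control_events = np.asarray(control_events, float)
    if stim_events.size == 0 or control_events.size == 0:
        raise ValidationError("both trial groups must be nonempty")
    st = unit.spike_times

    def counts(events: np.ndarray, window: tuple[float, float]) -> np.ndarray:
        lo = np.searchsorted(st, events + window[0], side="left")
        hi = np.searchsorted(st, events + window[1], side="left")
        return (hi - lo).astype(float)

    c_stim = counts(stim_events, stim)
    c_ctrl = counts(control_events, stim)
    if st.size == 0:
        zeros = np.zeros(1)
        return ModulationResult(zeros, zeros, np.ones(1),
                                np.array([False]), baseline, stim)
    p = stats.ranksums(c_stim, c_ctrl).pvalue

    # trial-averaged rate z against baseline, on the stimulated trials
    edges = np.arange(baseline[0], stim[1] + rate_bin_s / 2, rate_bin_s)
    hist = np.zeros(edges.size - 1)
    for ev in stim_events:
        hist += np.histogram(st - ev, bins=edges)[0]
    rate = hist / (stim_events.size * rate_bin_s)
    centers = edges[:-1] + rate_bin_s / 2
    base_mask = (centers >= baseline[0]) & (centers < baseline[1])
    stim_mask = (centers >= stim[0]) & (centers < stim[1])
    mu, sd = rate[base_mask].mean(), rate[base_mask].std(ddof=0)
    if sd == 0:
        z_prof = np.zeros_like(rate)
        max_z = 0.0
    else:
        z_prof = (rate - mu) / sd
        max_z = float(np.abs(z_prof[stim_mask]).max())
    modulated = (max_z > cfg.z_threshold) and (p < cfg.ranksum_alpha)
    return ModulationResult(z_prof, np.array([max_z]), np.array([p]),
                            np.array([modulated]), baseline, stim)


def _gaussian_kernel(sigma_s: float, bin_s: float) -> np.ndarray:
    half = max(1, int(np.ceil(4.0 * sigma_s / bin_s)))
    t = np.arange(-half, half + 1) * bin_s
    k = np.exp(-0.5 * (t / sigma_s) ** 2)
    return k / k.sum()


def compute_psth(spike_times: np.ndarray, events: np.ndarray,
                 window: tuple[float, float], sigma_s: float = 0.010,
                 bin_s: float = 0.001) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-smoothed PSTH in spikes/s.

    Returns ``(t, rate, sem)`` where ``t`` are bin centers relative to the
    event. Counts are binned at 1 ms, convolved with a unit-sum Gaussian
    kernel (truncated at ±4 sigma) per trial, then averaged across trials.
    """
    if sigma_s <= 0:
        raise ValueError("sigma must be > 0")
    spike_times = np.asarray(spike_times, float)
    events = np.atleast_1d(np.asarray(events, float))
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    kernel = _gaussian_kernel(sigma_s, bin_s)
    per_trial = np.empty((events.size, edges.size - 1))
    for i, ev in enumerate(events):
        counts = np.histogram(spike_times - ev, bins=edges)[0] / bin_s
        per_trial[i] = np.convolve(counts, kernel, mode="same")
    rate = per_trial.mean(axis=0)
    sem = per_trial.std(axis=0, ddof=1) / np.sqrt(events.size) if events.size > 1 \
        else np.zeros_like(rate)
    t = edges[:-1] + bin_s / 2
    return t, rate, sem


def autocorrelogram(spike_times: np.ndarray, bin_s: float = 0.00033,
                    span_s: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Normalized spike-train autocorrelogram.

    All pairwise lags within ±``span_s`` are histogrammed at ``bin_s``
    resolution; the central (zero-lag) bin is removed and the histogram is
    divided by its maximum. Returns ``(lags, acg)``; exactly symmetric.
    """
    st = np.asarray(spike_times, float)
    if st.size < 2:
        raise ValidationError("autocorrelogram needs at least 2 spikes")
    n_half = int(np.ceil(span_s / bin_s))
    # 2*n_half+1 bins with the central one straddling zero lag
    edges = (np.arange(-n_half - 1, n_half + 1) + 0.5) * bin_s
    pos = np.zeros(n_half)
    hi = np.searchsorted(st, st + span_s + bin_s, side="right")
    pos_edges = edges[n_half + 1:]
    for i in range(st.size):
        lags = st[i + 1: hi[i]] - st[i]
        pos += np.histogram(lags, bins=pos_edges)[0]
    counts = np.concatenate([pos[::-1], [0.0], pos])  # mirror; central bin removed
    peak = counts.max()
    if peak > 0:
        counts = counts / peak
    lags = 0.5 * (edges[:-1] + edges[1:])
    return lags, counts


def fit_orientation_tuning(orientations_deg: np.ndarray,
                           rates: np.ndarray,
                           sems: np.ndarray | None = None) -> TuningFit:
    """Least-squares von Mises fit R(theta) = b + a*exp(kappa*(cos(2(theta-
    theta_pref)) - 1)), 180 deg periodic. Descriptive only.
    """
    theta = np.asarray(orientations_deg, float)
    rates = np.asarray(rates, float)
    if np.unique(theta % 180.0).size < 4:
        raise ValidationError("need at least 4 distinct orientations")
    sems = np.zeros_like(rates) if sems is None else np.asarray(sems, float)
    if np.allclose(rates, rates[0]):
        return TuningFit(theta, rates, sems, float(rates[0]), 0.0, 0.0, 0.0, 0.0)

    th = np.deg2rad(theta)

    def model(params: np.ndarray) -> np.ndarray:
        b, a, kappa, pref = params
        return b + a * np.exp(kappa * (np.cos(2.0 * (th - pref)) - 1.0))

    best = None
    span = rates.max() - rates.min()
    for pref0 in np.deg2rad(np.arange(0.0, 180.0, 22.5)):
        x0 = np.array([rates.min(), span, 1.0, pref0])
        res = optimize.least_squares(
            lambda p: model(p) - rates, x0,
            bounds=([-np.inf, 0.0, 0.0, -np.pi], [np.inf, np.inf, 50.0, 2 * np.pi]),
        )
        if best is None or res.cost < best.cost:
            best = res
    b, a, kappa, pref = best.x
    pref_deg = float(np.rad2deg(pref) % 180.0)
    residual = float(np.sqrt(2.0 * best.cost / rates.size))
    return TuningFit(theta, rates, sems, float(b), float(a), float(kappa),
                     pref_deg, residual)


def firing_rate_stability(spike_times: np.ndarray, session_span: float,
                          sigma_s: float = 2.0,
                          edge_exclude_s: float = 5.0,
                          bin_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Session-long smoothed firing rate (Gaussian sigma 2 s), with the first
    and last 5 s excluded from the returned span. Returns ``(t, rate)``.
    """
    if session_span < 4 * edge_exclude_s:
        raise ValidationError("session too short for stability trace")
    st = np.asarray(spike_times, float)
    edges = np.arange(0.0, session_span + bin_s / 2, bin_s)
    counts = np.histogram(st, bins=edges)[0] / bin_s
    kernel = _gaussian_kernel(sigma_s, bin_s)
    rate = np.convolve(counts, kernel, mode="same")
    t = edges[:-1] + bin_s / 2
    keep = (t >= edge_exclude_s) & (t <= session_span - edge_exclude_s)
    return t[keep], rate[keep]
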