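"""Spike-cluster curation.

Clusters produced by an upstream sorter are accepted only if all three rules
hold: (1) no more than 2.5% of inter-spike intervals below 1.5 ms,
(2) the peak-channel mean waveform correlates at Pearson r >= 0.95 with at
least one of 20 reference "good" waveform templates, and (3) the waveform
footprint is concentrated within fewer than 5 channels (channels whose
peak-to-trough amplitude exceeds half the maximum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core.config import AnalysisConfig
from .core.types import SpikeCluster, ValidationError

__all__ = [
    "QCReport",
    "trimmed_mean_waveform",
    "isi_violation_check",
    "template_similarity_check",
    "spatial_spread_check",
    "default_template_library",
    "curate_clusters",
]


@dataclass
class QCReport:
    unit_id: int
    isi_violation_fraction: float
    isi_pass: bool
    max_template_r: float
    template_pass: bool
    spread_channels: int
    spread_pass: bool
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)


def trimmed_mean_waveform(snippets: np.ndarray,
                          trim_fraction: float = 0.05) -> np.ndarray:
    """Per-channel, per-sample trimmed mean across snippets (5% exclusion,
    2.5% per tail). Falls back to the plain mean with a warning below 20
    snippets.
    """
    snippets = np.asarray(snippets, dtype=np.float64)
    if snippets.ndim != 3:
        raise ValidationError("snippets must be (spikes, channels, samples)")
    if snippets.shape[0] < 20:
        warnings.warn("fewer than 20 snippets; using untrimmed mean",
                      stacklevel=2)
        return snippets.mean(axis=0)
    return stats.trim_mean(snippets, trim_fraction / 2.0, axis=0)


def isi_violation_check(spike_times: np.ndarray,
                        refractory_s: float = 0.0015,
                        limit: float = 0.025,
                        mode: str = "isi") -> tuple[float, bool]:
    """Fraction of inter-spike intervals below the refractory period.

    Passes when the fraction does not EXCEED the limit (boundary passes).
    ``mode="spikes"`` divides by the spike count instead of the ISI count.
    """
    st = np.asarray(spike_times, dtype=np.float64)
    if st.size < 2:
        raise ValidationError("need at least 2 spikes for an ISI check")
    if np.any(np.diff(st) < 0):
        raise ValidationError("spike times must be sorted")
    isis = np.diff(st)
    n_viol = int(np.count_nonzero(isis < refractory_s))
    denom = isis.size if mode == "isi" else st.size
    frac = n_viol / denom
    return frac, frac <= limit


def _resample_template(template: np.ndarray, n: int) -> np.ndarray:
    if template.size == n:
        return template
    x_old = np.linspace(0.0, 1.0, template.size)
    x_new = np.linspace(0.0, 1.0, n)
    return np.interp(x_new, x_old, template)


def template_similarity_check(waveform: np.ndarray,
                              templates: np.ndarray,
                              r_threshold: float = 0.95) -> tuple[float, bool]:
    """Max Pearson r between the peak-channel waveform and any template.

    A zero-variance waveform fails (r = -inf) rather than raising.
    """
    w = np.asarray(waveform, dtype=np.float64).ravel()
    if np.std(w) == 0:
        return float("-inf"), False
    best = -1.0
    for tmpl in np.atleast_2d(templates):
        t = _resample_template(np.asarray(tmpl, float), w.size)
        if np.std(t) == 0:
            continue
        best = max(best, float(np.corrcoef(w, t)[0, 1]))
    return best, best >= r_threshold


def spatial_spread_check(mean_waveform: np.ndarray,
                         channel_limit: int = 5) -> tuple[int, bool]:
    """Count channels whose peak-to-trough amplitude exceeds 50% of the
    maximum; pass when the count is strictly below ``channel_limit``.
    """
    mw = np.asarray(mean_waveform, dtype=np.float64)
    amp = np.ptp(mw, axis=1)
    peak = amp.max()
    if peak == 0:
        return 0, True
    n = int(np.count_nonzero(amp > 0.5 * peak))
    return n, n < channel_limit


def _biphasic(t: np.ndarray, trough_to_peak_s: float,
              trough_width_s: float) -> np.ndarray:
    """Canonical extracellular shape: sharp negative trough, slower positive
    rebound ``trough_to_peak_s`` later."""
    t0 = 4.0 * trough_width_s
    w = -np.exp(-0.5 * ((t - t0) / trough_width_s) ** 2)
    w += 0.45 * np.exp(-0.5 * ((t - t0 - trough_to_peak_s)
                               / (1.8 * trough_width_s)) ** 2)
    return w


def default_template_library(n_samples: int = 82,
                             rate: float = 25000.0) -> np.ndarray:
    """20 biphasic reference waveforms spanning trough-to-peak widths
    0.3-1.2 ms, generated deterministically. Shape ``(20, n_samples)``.
    """
    t = np.arange(n_samples) / rate
    widths = np.linspace(0.0003, 0.0012, 20)
    lib = np.stack([_biphasic(t, w, 0.25 * w + 0.00008) for w in widths])
    return lib / np.abs(lib).max(axis=1, keepdims=True)


def curate_clusters(clusters: list[SpikeCluster],
                    templates: np.ndarray | None = None,
                    config: AnalysisConfig | None = None) -> list[QCReport]:
    """Apply all three acceptance rules to every cluster.

    ``accepted`` requires all three to pass; ``rejection_reasons`` lists each
    failed rule ("isi", "template", "spread"). Order-independent.
    """
    cfg = config or AnalysisConfig()
    if templates is None:
        templates = default_template_library()
    reports = []
    for cl in clusters:
        mw = cl.mean_waveform
        if mw is None and cl.snippets is not None:
            mw = trimmed_mean_waveform(cl.snippets, cfg.waveform_trim_fraction)
        if mw is None:
            raise ValidationError(f"unit {cl.unit_id}: no waveform available")
        frac, isi_ok = isi_violation_check(
            cl.spike_times, cfg.isi_refractory_s, cfg.isi_violation_limit)
        peak = int(np.argmax(np.ptp(mw, axis=1)))
        r, tmpl_ok = template_similarity_check(
            mw[peak], templates, cfg.template_r_threshold)
        n_spread, spread_ok = spatial_spread_check(mw, cfg.spread_channel_limit)
        reasons = [name for name, ok in
                   (("isi", isi_ok), ("template", tmpl_ok), ("spread", spread_ok))
                   if not ok]
        reports.append(QCReport(
            unit_id=cl.unit_id,
            isi_violation_fraction=frac,
            isi_pass=isi_ok,
            max_template_r=r,
            template_pass=tmpl_ok,
            spread_channels=n_spread,
            spread_pass=spread_ok,
            accepted=not reasons,
            rejection_reasons=reasons,
        ))
    return reports
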