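"""Synthetic multichannel extracellular recordings with known ground truth.

A 25 kHz trace over one or more 32-site shanks (25 µm pitch) made of
Gaussian plus 1/f noise, with biphasic spike templates inserted at
ground-truth times. Unit amplitude decays across sites as exp(-d/40 µm).
Visual units fire from an inhomogeneous Poisson kernel after stimulus
onsets; opto-entrained units fire at a rate proportional to the laser
waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core.rng import seeded_rng
from ..core.types import ChannelInfo, RecordingBlock
from ..qc import _biphasic
from .laser import LaserWaveform

__all__ = ["SimUnit", "RecordingSimConfig", "RecordingGroundTruth",
           "simulate_recording", "make_channel_map"]

SITE_PITCH_UM = 25.0
SITES_PER_SHANK = 32
AMPLITUDE_LENGTH_UM = 40.0  # spatial decay constant of the template


@dataclass
class SimUnit:
    """Ground-truth description of one simulated unit."""

    unit_id: int
    depth_um: float
    shank: int = 0
    amplitude_uV: float = 120.0
    modulation: str = "none"  # none | visual | opto-entrained | suppressed
    baseline_rate: float = 5.0  # spikes/s
    evoked_rate: float = 60.0  # peak added rate for visual units
    entrainment_freq: float = 80.0  # Hz, opto-entrained units
    entrainment_sharpness: float = 1.0  # exponent on the normalized drive;
    # > 1 concentrates spikes near the crest (tight phase locking)
    adaptation_tau_s: float | None = None  # within-burst rate adaptation
    trough_to_peak_s: float = 0.0006


@dataclass
class RecordingSimConfig:
    duration: float = 2.0
    rate: float = 25000.0
    n_shanks: int = 1
    noise_sigma_uV: float = 10.0
    pink_fraction: float = 0.3  # share of noise power given to the 1/f term
    units: list[SimUnit] = field(default_factory=list)
    stim_onsets: tuple[float, ...] = ()
    stim_duration: float = 0.65
    laser: LaserWaveform | None = None
    laser_onsets: tuple[float, ...] = ()


@dataclass
class RecordingGroundTruth:
    spike_times: dict[int, np.ndarray]  # unit_id -> times (s)
    units: list[SimUnit]
    template_trough_offset_s: float  # trough lag of the inserted template


def make_channel_map(n_shanks: int = 1,
                     sites: int = SITES_PER_SHANK) -> list[ChannelInfo]:
    return [ChannelInfo(shank=s, index=i, depth_um=i * SITE_PITCH_UM)
            for s in range(n_shanks) for i in range(sites)]


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.where(freqs > 0, 1.0 / np.sqrt(freqs + freqs[1]), 0.0)
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _thin_inhomogeneous(rate_fn: np.ndarray, dt: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Spike times (bin centers) from a per-bin rate array via Bernoulli
    thinning; adequate for rate*dt << 1."""
    p = np.clip(rate_fn * dt, 0.0, 1.0)
    hits = rng.random(p.size) < p
    return (np.flatnonzero(hits) + 0.5) * dt


def _unit_rate(unit: SimUnit, cfg: RecordingSimConfig,
               t: np.ndarray) -> np.ndarray:
    rate = np.full(t.size, unit.baseline_rate)
    if unit.modulation == "visual":
        for onset in cfg.stim_onsets:
            tau = 0.05
            rel = t - onset
            mask = (rel >= 0) & (rel < cfg.stim_duration)
            rate[mask] += unit.evoked_rate * (rel[mask] / tau) \
                * np.exp(1.0 - rel[mask] / tau)
    elif unit.modulation == "suppressed":
        for onset in cfg.stim_onsets:
            mask = (t >= onset) & (t < onset + cfg.stim_duration)
            rate[mask] *= 0.1
    elif unit.modulation == "opto-entrained":
        if cfg.laser is None:
            raise ValueError("opto-entrained unit requires a laser waveform")
        w = (cfg.laser.samples / cfg.laser.peak) ** unit.entrainment_sharpness
        for onset in cfg.laser_onsets:
            i0 = int(round(onset * cfg.rate))
            seg = w[: max(0, min(w.size, t.size - i0))].copy()
            if unit.adaptation_tau_s is not None:
                rel = np.arange(seg.size) / cfg.rate
                seg *= np.exp(-rel / unit.adaptation_tau_s)
            rate[i0: i0 + seg.size] += unit.evoked_rate * seg
    elif unit.modulation != "none":
        raise ValueError(f"unknown modulation {unit.modulation!r}")
    return rate


def simulate_recording(cfg: RecordingSimConfig, seed: int = 0,
                       ) -> tuple[RecordingBlock, RecordingGroundTruth]:
    """Generate a recording block and its ground truth. Reproducible:
    identical (cfg, seed) give identical output."""
    rng = seeded_rng(seed, "recording")
    cmap = make_channel_map(cfg.n_shanks)
    n = int(round(cfg.duration * cfg.rate))
    n_ch = len(cmap)
    depth_span = (SITES_PER_SHANK - 1) * SITE_PITCH_UM

    if cfg.noise_sigma_uV > 0:
        w = np.sqrt(1.0 - cfg.pink_fraction)
        p = np.sqrt(cfg.pink_fraction)
        trace = cfg.noise_sigma_uV * (
            w * rng.standard_normal((n_ch, n)) + p * _pink_noise((n_ch, n), rng)
        )
    else:
        trace = np.zeros((n_ch, n))

    t = np.arange(n) / cfg.rate
    n_wave = 82
    wave_t = np.arange(n_wave) / cfg.rate
    depths = np.array([c.depth_um for c in cmap])
    shanks = np.array([c.shank for c in cmap])

    spike_times: dict[int, np.ndarray] = {}
    trough_offset = 0.0
    for unit in cfg.units:
        if not 0.0 <= unit.depth_um <= depth_span:
            raise ValueError(
                f"unit {unit.unit_id} depth {unit.depth_um} outside probe span")
        template = _biphasic(wave_t, unit.trough_to_peak_s,
                             0.25 * unit.trough_to_peak_s + 0.00008)
        template = template / -template.min()  # trough = -1
        trough_offset = float(np.argmin(template)) / cfg.rate
        times = _thin_inhomogeneous(_unit_rate(unit, cfg, t), 1.0 / cfg.rate, rng)
        times = times[times < cfg.duration - n_wave / cfg.rate]
        spike_times[unit.unit_id] = times
        gain = np.where(
            shanks == unit.shank,
            unit.amplitude_uV * np.exp(-np.abs(depths - unit.depth_um)
                                       / AMPLITUDE_LENGTH_UM),
            0.0,
        )
        idx = np.round(times * cfg.rate).astype(int)
        for i in idx:
            trace[:, i: i + n_wave] += gain[:, None] * template[None, :]

    block = RecordingBlock(trace, cfg.rate, cmap)
    return block, RecordingGroundTruth(spike_times, list(cfg.units),
                                       trough_offset)
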