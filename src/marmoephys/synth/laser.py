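"""Optical stimulation waveform synthesis.

Sinusoidal drive starts smoothly at its trough (0 mW) and peaks at the
commanded power; square pulses get half-sine edge tapers with a 5 ms
trough-to-peak time so light intensity never jumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LaserWaveform", "make_laser_waveform"]


@dataclass
class LaserWaveform:
    samples: np.ndarray  # optical power, mW
    rate: float
    freq: float
    peak: float
    phase: float
    taper: float  # trough-to-peak edge time, s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


def make_laser_waveform(freq: float, duration: float, peak: float,
                        phase: float = 0.0, rate: float = 25000.0,
                        taper: float = 0.005) -> LaserWaveform:
    """Synthesize a laser power waveform.

    For ``freq > 0``: a sinusoid oscillating between 0 and ``peak`` mW
    (amplitude peak/2 about peak/2) that starts at its trough when
    ``phase = 0``; edge tapers force exact zeros at the first and last
    sample. For ``freq = 0``: a constant ``peak`` plateau with half-sine
    tapers of ``taper`` trough-to-peak time at both edges.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if freq < 0 or peak <= 0:
        raise ValueError("freq must be >= 0 and peak > 0")
    if duration < 2 * taper:
        raise ValueError("duration shorter than the two edge tapers")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if freq > 0:
        # -cos puts the trough at t=0 for phase 0
        w = 0.5 * peak * (1.0 - np.cos(2.0 * np.pi * freq * t + phase))
    else:
        w = np.full(n, peak)
    n_taper = int(round(taper * rate))
    if n_taper > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))
        w[:n_taper] *= ramp
        w[-n_taper:] *= ramp[::-1]
    w[0] = 0.0
    w[-1] = 0.0
    np.clip(w, 0.0, peak, out=w)
    return LaserWaveform(w, rate, freq, peak, phase, taper)
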