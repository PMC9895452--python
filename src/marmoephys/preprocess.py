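"""Raw-trace conditioning: resampling, re-referencing, spike-band filtering,
MUA envelope extraction and event-aligned epoching.

The chain is: polyphase resampling of the 24414.0625 Hz acquisition rate to
exactly 25 kHz (ratio 128/125), per-shank common-median subtraction,
spike-band filtering (4th-order Butterworth 0.3-6 kHz, or a 40th-order
Chebyshev II 0.3-8 kHz with 200 dB stopband attenuation when optical
stimulation contaminates low frequencies), then full-wave rectification,
a 6th-order low-pass Chebyshev II (stopband edge 500 Hz, 50 dB) and
decimation to 1 kHz. Filters run causally as second-order-section cascades;
group-delay latency shifts are documented, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core.types import RecordingBlock, ValidationError

__all__ = [
    "MUASeries",
    "TrialTensor",
    "ACQUISITION_RATE",
    "TARGET_RATE",
    "MUA_RATE",
    "resample_to_25k",
    "median_rereference",
    "spikeband_sos",
    "bandpass_spikeband",
    "compute_mua",
    "epoch_align",
]

ACQUISITION_RATE = 24414.0625  # 25 MHz / 1024
TARGET_RATE = 25000.0
MUA_RATE = 1000.0

_RESAMPLE_UP = 128
_RESAMPLE_DOWN = 125

SPIKEBAND_DESIGNS = ("butter4_300_6000", "cheby2_40_300_8000")


@dataclass
class MUASeries:
    """Per-channel nonnegative 1 kHz envelope (arbitrary µV units)."""

    values: np.ndarray  # (channels, time), >= 0
    rate: float
    t0: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rate != MUA_RATE:
            raise ValidationError(f"MUA rate must be {MUA_RATE} Hz, got {self.rate}")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("MUA values must be nonnegative")


@dataclass
class TrialTensor:
    """Event-aligned ``(trials, channels, time)`` array."""

    values: np.ndarray
    rate: float
    window: tuple[float, float]  # seconds relative to the alignment event
    event: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("trial tensor must be 3-D (trials, channels, time)")
        n_expect = int(round((self.window[1] - self.window[0]) * self.rate))
        if self.values.shape[2] != n_expect:
            raise ValidationError(
                f"time axis {self.values.shape[2]} != window span {n_expect}"
            )

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to the alignment event."""
        n = self.values.shape[2]
        return self.window[0] + np.arange(n) / self.rate

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Integer sample slice for a half-open sub-window of the tensor."""
        lo = int(round((window[0] - self.window[0]) * self.rate))
        hi = int(round((window[1] - self.window[0]) * self.rate))
        if lo < 0 or hi > self.values.shape[2] or hi <= lo:
            raise ValidationError(f"window {window} outside tensor span {self.window}")
        return slice(lo, hi)


def resample_to_25k(block: RecordingBlock) -> RecordingBlock:
    """Rational-polyphase resample from 24414.0625 Hz to exactly 25 kHz.

    Output length is ``round(n * 128/125)``. Traces already at 25 kHz pass
    through unchanged (with a no-op); other rates are an error.
    """
    if np.isclose(block.rate, TARGET_RATE):
        return block
    if not np.isclose(block.rate, ACQUISITION_RATE):
        raise ValidationError(
            f"expected input rate {ACQUISITION_RATE} Hz, got {block.rate}"
        )
    # beta=18 keeps passband (DC..8 kHz) flat to < 0.01 dB
    out = signal.resample_poly(block.samples, _RESAMPLE_UP, _RESAMPLE_DOWN,
                               axis=1, window=("kaiser", 18.0))
    n_out = int(round(Fraction(block.n_samples) * _RESAMPLE_UP / _RESAMPLE_DOWN))
    if out.shape[1] > n_out:
        out = out[:, :n_out]
    elif out.shape[1] < n_out:  # pragma: no cover - resample_poly returns ceil
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])))
    return RecordingBlock(out, TARGET_RATE, block.channel_map, block.t0)


def median_rereference(block: RecordingBlock) -> RecordingBlock:
    """Subtract, per sample, the median across each shank's channels."""
    out = block.samples.copy()
    for shank in block.shanks:
        idx = block.shank_channels(shank)
        if idx.size == 0:
            raise ValidationError(f"shank {shank} has no channels")
        out[idx] -= np.median(out[idx], axis=0, keepdims=True)
    return RecordingBlock(out, block.rate, block.channel_map, block.t0)


def spikeband_sos(design: str, rate: float) -> np.ndarray:
    """Second-order sections for a named spike-band design at ``rate``.

    ``butter4_300_6000``: 4th-order Butterworth band-pass 0.3-6 kHz.
    ``cheby2_40_300_8000``: 20th-order Chebyshev II high-pass at 300 Hz
    cascaded with a 20th-order Chebyshev II low-pass at 8 kHz, 200 dB
    stopband attenuation each (40th order total).
    """
    if design == "butter4_300_6000":
        sos = signal.butter(4, [300.0, 6000.0], btype="bandpass", fs=rate,
                            output="sos")
    elif design == "cheby2_40_300_8000":
        hp = signal.cheby2(20, 200.0, 300.0, btype="highpass", fs=rate,
                           output="sos")
        lp = signal.cheby2(20, 200.0, 8000.0, btype="lowpass", fs=rate,
                           output="sos")
        sos = np.vstack([hp, lp])
    else:
        raise ValueError(f"unknown spike-band design {design!r}")
    # poles of each biquad must sit inside the unit circle
    for sec in sos:
        if np.any(np.abs(np.roots(sec[3:])) >= 1.0):
            raise ValidationError(f"design {design!r} unstable at rate {rate}")
    return sos


def bandpass_spikeband(block: RecordingBlock,
                       design: str = "butter4_300_6000") -> RecordingBlock:
    """Causal SOS spike-band filter; see :func:`spikeband_sos`."""
    if block.rate < TARGET_RATE:
        raise ValidationError("spike-band filtering expects rate >= 25 kHz")
    sos = spikeband_sos(design, block.rate)
    out = signal.sosfilt(sos, block.samples, axis=1)
    return RecordingBlock(out, block.rate, block.channel_map, block.t0)


def compute_mua(block: RecordingBlock) -> MUASeries:
    """Full-wave rectify, low-pass (cheby2 N=6, 500 Hz edge, 50 dB) and
    decimate to 1 kHz. Negative filter-ringing values are clipped at 0.

    Decimation keeps input sample 0 as the first output sample.
    """
    factor = block.rate / MUA_RATE
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError(
            f"rate {block.rate} not an integer multiple of {MUA_RATE} Hz"
        )
    sos = signal.cheby2(6, 50.0, 500.0, btype="lowpass", fs=block.rate,
                        output="sos")
    env = signal.sosfilt(sos, np.abs(block.samples), axis=1)
    env = env[:, :: int(round(factor))]
    np.clip(env, 0.0, None, out=env)
    return MUASeries(env, MUA_RATE, t0=block.t0,
                     provenance=f"rectify+cheby2_6_500_50@{block.rate:g}")


def epoch_align(series: MUASeries, events: np.ndarray,
                window: tuple[float, float], event_name: str = "") -> TrialTensor:
    """Cut ``series`` into per-event epochs over a half-open window.

    Raises a :class:`ValidationError` listing any events whose window falls
    outside the series span.
    """
    events = np.atleast_1d(np.asarray(events, dtype=np.float64))
    n_time = series.values.shape[1]
    n_win = int(round((window[1] - window[0]) * series.rate))
    starts = np.round((events + window[0] - series.t0) * series.rate).astype(int)
    bad = events[(starts < 0) | (starts + n_win > n_time)]
    if bad.size:
        raise ValidationError(f"events outside series span: {bad.tolist()}")
    trials = np.stack([series.values[:, s: s + n_win] for s in starts])
    return TrialTensor(trials, series.rate, window, event_name)
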