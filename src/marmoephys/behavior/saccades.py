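"""Velocity-threshold saccade detection from 1 kHz eye traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core.types import EyeTrace, ValidationError

__all__ = ["SaccadeEvent", "detect_saccades"]


@dataclass
class SaccadeEvent:
    onset: float  # s, absolute
    offset: float  # s, absolute
    endpoint: tuple[float, float]  # (x, y) degrees; NaN if undefined
    amplitude: float  # degrees
    direction: float  # degrees CCW from +x
    endpoint_defined: bool = True


def detect_saccades(eye: EyeTrace,
                    velocity_threshold: float = 50.0,
                    smooth_sigma_s: float = 0.003,
                    merge_gap_s: float = 0.010,
                    endpoint_window_s: float = 0.025) -> list[SaccadeEvent]:
    """Detect saccades as maximal runs of speed above threshold.

    Position is Gaussian-smoothed (sigma 3 ms) before central-difference
    velocity; runs separated by less than ``merge_gap_s`` merge into one
    event. The endpoint is the per-axis median over the 25 ms after offset;
    amplitude and direction run from the pre-onset fixation median (25 ms
    before onset) to the endpoint. Blink samples are treated as
    below-threshold. A saccade at the trace end with no room for the
    endpoint window is flagged ``endpoint_defined=False``.
    """
    n = eye.t.size
    if n < int(0.05 * eye.rate):
        raise ValidationError("eye trace shorter than 50 ms")
    sigma = smooth_sigma_s * eye.rate
    xs = ndimage.gaussian_filter1d(eye.x, sigma, mode="nearest")
    ys = ndimage.gaussian_filter1d(eye.y, sigma, mode="nearest")
    vx = np.gradient(xs) * eye.rate
    vy = np.gradient(ys) * eye.rate
    speed = np.hypot(vx, vy)
    if eye.blink.any():
        # widen the mask past the smoothing kernel so lid-closure edges
        # cannot masquerade as saccades
        pad = int(np.ceil(3 * sigma)) + 2
        masked = ndimage.binary_dilation(eye.blink, iterations=pad)
        speed[masked] = 0.0

    above = speed > velocity_threshold
    if not above.any():
        return []
    # runs of consecutive above-threshold samples
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    stops = np.flatnonzero(above & ~np.roll(above, -1)) + 1
    if above[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    if above[-1]:
        stops = np.unique(np.concatenate([stops, [n]]))

    # merge runs separated by short gaps
    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * eye.rate))
    for s, e in zip(starts, stops):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    win = int(round(endpoint_window_s * eye.rate))
    events = []
    for s, e in merged:
        defined = e + win <= n
        if defined:
            ex = float(np.median(eye.x[e: e + win]))
            ey = float(np.median(eye.y[e: e + win]))
        else:
            ex = ey = float("nan")
        p0 = max(0, s - win)
        fx = float(np.median(eye.x[p0:s])) if s > p0 else float(eye.x[s])
        fy = float(np.median(eye.y[p0:s])) if s > p0 else float(eye.y[s])
        dx, dy = ex - fx, ey - fy
        amp = float(np.hypot(dx, dy)) if defined else float("nan")
        direction = float(np.rad2deg(np.arctan2(dy, dx)) % 360.0) if defined \
            else float("nan")
        events.append(SaccadeEvent(
            onset=float(eye.t[s]),
            offset=float(eye.t[min(e, n - 1)]),
            endpoint=(ex, ey),
            amplitude=amp,
            direction=direction,
            endpoint_defined=defined,
        ))
    return events
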