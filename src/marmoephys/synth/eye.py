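"""Synthetic 1 kHz eye traces: mean-reverting fixational jitter plus
velocity-profiled saccades with ground-truth onsets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core.rng import seeded_rng
from ..core.types import EyeTrace, TrialTable, ValidationError

__all__ = ["SaccadePlan", "EyeSimParams", "EyeGroundTruth",
           "simulate_eye_trace", "schedule_from_trials"]


@dataclass(frozen=True)
class SaccadePlan:
    onset: float  # s
    amplitude: float  # degrees
    direction: float  # degrees CCW from +x

    @property
    def sigma(self) -> float:
        """Velocity-profile width; scales mildly with amplitude and keeps
        peak speed above 50 deg/s down to 0.5 deg saccades."""
        return 0.003 + 0.001 * self.amplitude

    @property
    def duration(self) -> float:
        # +/- 2 sigma support: the pulse edge is where motion becomes
        # appreciable, so the detector's threshold crossing stays within a
        # few ms of the ground-truth onset
        return 4.0 * self.sigma


@dataclass
class EyeSimParams:
    rate: float = 1000.0
    jitter_sigma: float = 0.05  # deg, stationary SD of fixational jitter
    jitter_tau: float = 0.05  # s, mean-reversion time constant
    blink_times: tuple[float, ...] = ()
    blink_duration: float = 0.08
    start: tuple[float, float] = (0.0, 0.0)


@dataclass
class EyeGroundTruth:
    onsets: np.ndarray
    offsets: np.ndarray
    amplitudes: np.ndarray
    directions: np.ndarray


def schedule_from_trials(trials: TrialTable, amplitude: float = 8.0,
                         direction: float = -72.7) -> list[SaccadePlan]:
    """Plan one saccade per trial that has a response time, aimed at the
    target's polar direction."""
    plans = []
    for row in trials.df.itertuples(index=False):
        if not np.isnan(row.response_time):
            plans.append(SaccadePlan(float(row.response_time), amplitude,
                                     direction))
    return plans


def simulate_eye_trace(schedule: list[SaccadePlan] | TrialTable,
                       duration: float, params: EyeSimParams | None = None,
                       seed: int = 0) -> tuple[EyeTrace, EyeGroundTruth]:
    """Generate a gaze trace containing the scheduled saccades.

    Each saccade is a Gaussian-profile velocity pulse; the ground-truth
    onset is the first sample of the pulse. Overlapping saccades are an
    error. Blink periods excurse downward and are flagged in the mask.
    """
    params = params or EyeSimParams()
    if isinstance(schedule, TrialTable):
        schedule = schedule_from_trials(schedule)
    schedule = sorted(schedule, key=lambda p: p.onset)
    for a, b in zip(schedule, schedule[1:]):
        if a.onset + a.duration > b.onset:
            raise ValidationError(
                f"saccades at {a.onset:.3f}s and {b.onset:.3f}s overlap")

    rng = seeded_rng(seed, "eye")
    rate = params.rate
    n = int(round(duration * rate))
    dt = 1.0 / rate
    t = np.arange(n) * dt

    # OU fixational jitter per axis
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = params.start
    if params.jitter_sigma > 0:
        a = dt / params.jitter_tau
        s = params.jitter_sigma * np.sqrt(2.0 * a)
        ex = rng.standard_normal(n - 1)
        ey = rng.standard_normal(n - 1)
        for i in range(1, n):
            x[i] = x[i - 1] + a * (params.start[0] - x[i - 1]) + s * ex[i - 1]
            y[i] = y[i - 1] + a * (params.start[1] - y[i - 1]) + s * ey[i - 1]
    else:
        x[:] = params.start[0]
        y[:] = params.start[1]

    onsets, offsets = [], []
    for plan in schedule:
        i0 = int(round(plan.onset * rate))
        n_sac = int(round(plan.duration * rate))
        if i0 + n_sac > n:
            raise ValidationError(f"saccade at {plan.onset}s exceeds trace span")
        tt = (np.arange(n_sac) + 0.5) * dt
        mid = plan.duration / 2.0
        v = np.exp(-0.5 * ((tt - mid) / plan.sigma) ** 2)
        disp = np.cumsum(v)
        disp *= plan.amplitude / disp[-1]
        th = np.deg2rad(plan.direction)
        x[i0: i0 + n_sac] += disp * np.cos(th)
        y[i0: i0 + n_sac] += disp * np.sin(th)
        x[i0 + n_sac:] += plan.amplitude * np.cos(th)
        y[i0 + n_sac:] += plan.amplitude * np.sin(th)
        onsets.append(i0 * dt)
        offsets.append((i0 + n_sac) * dt)

    blink = np.zeros(n, dtype=bool)
    for bt in params.blink_times:
        b0 = int(round(bt * rate))
        b1 = min(n, b0 + int(round(params.blink_duration * rate)))
        blink[b0:b1] = True
        y[b0:b1] -= 30.0  # lid-closure artifact excursion

    eye = EyeTrace(t=t, x=x, y=y, rate=rate, blink=blink)
    gt = EyeGroundTruth(
        onsets=np.array(onsets),
        offsets=np.array(offsets),
        amplitudes=np.array([p.amplitude for p in schedule]),
        directions=np.array([p.direction for p in schedule]),
    )
    return eye, gt
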