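"""Synthetic detection-task sessions.

``simulate_detection_session`` draws a random session from per-condition hit
probabilities plus a time-homogeneous false-alarm hazard, leaving outcomes
unscored (scoring is the pipeline's job). ``make_fixture_fig8_session``
builds the deterministic worked-example session whose per-condition totals
and responder counts equal the published detection-task count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core.rng import seeded_rng
from ..core.types import TRIAL_COLUMNS, TrialTable, ValidationError

__all__ = [
    "SessionPsychometrics",
    "SessionGroundTruth",
    "simulate_detection_session",
    "FIG8B_TOTALS",
    "FIG8B_RESPONDERS",
    "make_fixture_fig8_session",
]

#: Per-condition trial totals of the worked-example session.
FIG8B_TOTALS = {
    "high": 115,
    "high+opto": 123,
    "low": 118,
    "low+opto": 109,
    "opto_only": 119,
    "sham": 116,
    "catch": 467,
}

#: Responder counts: hit trials per go condition; false alarms for catch
#: (the catch count is the nearest integer consistent with the published
#: 33.4% false-alarm rate at n = 467).
FIG8B_RESPONDERS = {
    "high": 108,
    "high+opto": 109,
    "low": 66,
    "low+opto": 89,
    "opto_only": 53,
    "sham": 44,
    "catch": 156,
}


@dataclass
class SessionPsychometrics:
    hit_prob: dict[str, float]  # per go condition
    fa_hazard: float = 0.1  # false alarms / s, from background onset
    catch_fraction: float = 0.4
    rt_median: float = 0.25  # s, log-normal latency
    rt_sigma_log: float = 0.3

    def __post_init__(self) -> None:
        for cond, p in self.hit_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"hit probability for {cond} outside [0,1]")
        if self.fa_hazard < 0:
            raise ValidationError("false-alarm hazard must be >= 0")


@dataclass
class SessionGroundTruth:
    hit_prob: dict[str, float]
    fa_hazard: float
    intended_hit: np.ndarray  # bool per trial: drawn as a hit (go trials)
    fa_time: np.ndarray  # s after background_on, NaN if none drawn


_TRIAL_GAP = 1.0  # s between fixation onsets of consecutive trials
_CATCH_SPAN = 0.8  # required catch fixation
_TARGET_DELAY = (0.150, 0.320)  # after background onset
_FIX_SPAN = (0.100, 0.150)


def _truncated_lognormal(rng: np.random.Generator, median: float,
                         sigma_log: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        v = float(rng.lognormal(np.log(median), sigma_log))
        if lo <= v < hi:
            return v
    return 0.5 * (lo + hi)  # pragma: no cover - pathological parameters


def simulate_detection_session(psych: SessionPsychometrics, n_trials: int,
                               seed: int = 0,
                               hit_window: tuple[float, float] = (0.05, 0.5),
                               ) -> tuple[TrialTable, SessionGroundTruth]:
    """Draw a session: 40% catch trials, the rest split evenly over the go
    conditions in ``psych.hit_prob``. Go responses occur with the
    per-condition hit probability at a truncated log-normal latency; false
    alarms arrive from a homogeneous hazard starting at background onset and
    preempt slower hits. Outcomes are left unscored.
    """
    rng = seeded_rng(seed, "session")
    go_conds = list(psych.hit_prob)
    n_catch = int(round(n_trials * psych.catch_fraction))
    conds = ["catch"] * n_catch + [
        go_conds[i % len(go_conds)] for i in range(n_trials - n_catch)
    ]
    rng.shuffle(conds)

    rows = []
    intended = np.zeros(n_trials, dtype=bool)
    fa_times = np.full(n_trials, np.nan)
    t_cursor = 0.0
    for i, cond in enumerate(conds):
        fixation_on = t_cursor
        background_on = fixation_on + rng.uniform(*_FIX_SPAN)
        target_on = laser_on = np.nan
        response = np.nan
        if cond == "catch":
            trial_end = background_on + _CATCH_SPAN
        else:
            onset = background_on + rng.uniform(*_TARGET_DELAY)
            if cond in ("high", "high+opto", "low", "low+opto"):
                target_on = onset
            if cond in ("high+opto", "low+opto", "opto_only", "sham"):
                laser_on = onset
            trial_end = onset + hit_window[1]
            if rng.random() < psych.hit_prob[cond]:
                intended[i] = True
                response = onset + _truncated_lognormal(
                    rng, psych.rt_median, psych.rt_sigma_log, *hit_window)
        if psych.fa_hazard > 0:
            fa = float(rng.exponential(1.0 / psych.fa_hazard))
            if background_on + fa < trial_end:
                fa_times[i] = fa
                if np.isnan(response) or background_on + fa < response:
                    response = background_on + fa
        rows.append({
            "trial_id": i,
            "condition": cond,
            "fixation_on": fixation_on,
            "background_on": background_on,
            "target_on": target_on,
            "laser_on": laser_on,
            "response_time": response,
            "outcome": "",
        })
        t_cursor = trial_end + _TRIAL_GAP
    table = TrialTable(pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)))
    return table, SessionGroundTruth(dict(psych.hit_prob), psych.fa_hazard,
                                     intended, fa_times)


def make_fixture_fig8_session() -> TrialTable:
    """Deterministic worked-example session.

    Per-condition totals and responder counts equal the published tables
    (see ``FIG8B_TOTALS`` / ``FIG8B_RESPONDERS``); response latencies are
    placeholders spread across the hit window (go) or the catch fixation
    span (catch false alarms).
    """
    rows = []
    trial_id = 0
    t_cursor = 0.0
    for cond in FIG8B_TOTALS:
        total = FIG8B_TOTALS[cond]
        responders = FIG8B_RESPONDERS[cond]
        for k in range(total):
            fixation_on = t_cursor
            background_on = fixation_on + 0.125
            target_on = laser_on = np.nan
            response = np.nan
            if cond == "catch":
                trial_end = background_on + _CATCH_SPAN
                if k < responders:
                    # spread across the catch fixation span
                    response = background_on + 0.06 + 0.70 * (k / responders)
            else:
                onset = background_on + 0.235
                if cond in ("high", "high+opto", "low", "low+opto"):
                    target_on = onset
                if cond in ("high+opto", "low+opto", "opto_only", "sham"):
                    laser_on = onset
                trial_end = onset + 0.5
                if k < responders:
                    # deterministic latencies inside the [50, 500) ms window
                    response = onset + 0.10 + 0.35 * (k / responders)
            rows.append({
                "trial_id": trial_id,
                "condition": cond,
                "fixation_on": fixation_on,
                "background_on": background_on,
                "target_on": target_on,
                "laser_on": laser_on,
                "response_time": response,
                "outcome": "",
            })
            trial_id += 1
            t_cursor = trial_end + _TRIAL_GAP
    return TrialTable(pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)))
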