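"""Trial-outcome scoring and per-condition response rates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..core.types import (
    LASER_ONLY_CONDITIONS,
    VISUAL_CONDITIONS,
    TrialTable,
    ValidationError,
)
from .saccades import SaccadeEvent

__all__ = ["ConditionRates", "classify_trial_outcomes", "condition_rates",
           "reference_onset"]


@dataclass
class ConditionRates:
    """Responders/total per condition with 95% Clopper-Pearson intervals."""

    conditions: list[str]
    responders: dict[str, int]
    totals: dict[str, int]
    rates: dict[str, float]
    ci: dict[str, tuple[float, float]]


def reference_onset(row) -> float:
    """Per-trial reference onset: target for visual conditions, laser for
    opto-only/sham, NaN for catch."""
    if row.condition in VISUAL_CONDITIONS:
        return row.target_on
    if row.condition in LASER_ONLY_CONDITIONS:
        return row.laser_on
    return float("nan")


def _response_times(trials: TrialTable,
                    saccades: list[SaccadeEvent] | None) -> np.ndarray:
    """Absolute response time per trial: the first saccade onset at or after
    the trial's background onset (when saccades are supplied), else the
    table's ``response_time`` column."""
    df = trials.df
    if saccades is None:
        return df["response_time"].to_numpy(dtype=float)
    onsets = np.sort([s.onset for s in saccades])
    rt = np.full(len(df), np.nan)
    # search within each trial's span: background_on .. next fixation_on
    fix = df["fixation_on"].to_numpy(dtype=float)
    ends = np.append(fix[1:], np.inf)
    bg = df["background_on"].to_numpy(dtype=float)
    for i, (b, e) in enumerate(zip(bg, ends)):
        if np.isnan(b):
            continue
        j = np.searchsorted(onsets, b)
        if j < onsets.size and onsets[j] < e:
            rt[i] = onsets[j]
    return rt


def classify_trial_outcomes(trials: TrialTable,
                            saccades: list[SaccadeEvent] | None = None,
                            hit_window: tuple[float, float] = (0.05, 0.5),
                            catch_fixation_s: float = 0.8) -> TrialTable:
    """Assign one outcome to every non-excluded trial.

    Go trials: a response with latency in ``[50, 500)`` ms after the
    reference onset is a hit; faster than 50 ms is early; none is a miss.
    Catch trials: any response within 800 ms of background onset is a false
    alarm, otherwise a correct rejection.
    """
    df = trials.df.copy()
    rts = _response_times(trials, saccades)
    outcomes = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.outcome == "excluded":
            outcomes.append("excluded")
            continue
        rt = rts[i]
        if row.condition == "catch":
            if np.isnan(row.background_on):
                raise ValidationError(f"trial {row.trial_id}: catch trial "
                                      "lacks background onset")
            responded = not np.isnan(rt) and \
                (rt - row.background_on) < catch_fixation_s
            outcomes.append("false_alarm" if responded else "correct_rejection")
            continue
        ref = reference_onset(row)
        if np.isnan(ref):
            raise ValidationError(
                f"trial {row.trial_id}: go trial lacks its reference onset")
        if np.isnan(rt):
            outcomes.append("miss")
            continue
        lat = rt - ref
        if hit_window[0] <= lat < hit_window[1]:
            outcomes.append("hit")
        elif lat < hit_window[0]:
            outcomes.append("early")
        else:
            outcomes.append("miss")
        df.loc[df.index[i], "response_time"] = rt
    df["outcome"] = outcomes
    return TrialTable(df)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def condition_rates(trials: TrialTable, conf: float = 0.95) -> ConditionRates:
    """Response rate per condition: hits/(hits+misses) for go conditions,
    false alarms/(FA+CR) for catch. Early/excluded trials do not count
    toward the totals."""
    df = trials.df
    conds, responders, totals, rates, cis = [], {}, {}, {}, {}
    for cond, grp in df.groupby("condition", sort=False):
        if cond == "catch":
            k = int((grp["outcome"] == "false_alarm").sum())
            n = int(grp["outcome"].isin(["false_alarm",
                                         "correct_rejection"]).sum())
        else:
            k = int((grp["outcome"] == "hit").sum())
            n = int(grp["outcome"].isin(["hit", "miss"]).sum())
        if n == 0:
            import warnings
            warnings.warn(f"condition {cond!r} has no scored trials; omitted",
                          stacklevel=2)
            continue
        conds.append(cond)
        responders[cond], totals[cond] = k, n
        rates[cond] = k / n
        cis[cond] = clopper_pearson(k, n, conf)
    return ConditionRates(conds, responders, totals, rates, cis)
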