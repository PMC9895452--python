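"""Bias-corrected false-alarm estimation and pairwise proportion tests.

Catch trials run longer than go trials, so the raw catch saccade rate
overstates the false-alarm rate. The correction pairs random catch trials
with random go trials and scores a false alarm only when the catch saccade
would have landed inside the paired go trial's hit window; rates and
Clopper-Pearson intervals are averaged over the resampling repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..core.rng import seeded_rng
from ..core.types import TrialTable, ValidationError
from .outcomes import reference_onset

__all__ = [
    "FIG8B_CONTRASTS",
    "CorrectedFARate",
    "corrected_false_alarm_rate",
    "corrected_fa_from_trials",
    "pairwise_rate_tests",
]

#: The five planned condition contrasts of the detection task.
FIG8B_CONTRASTS = (
    ("high", "low"),
    ("high", "high+opto"),
    ("low", "low+opto"),
    ("opto_only", "catch"),
    ("sham", "catch"),
)


@dataclass
class CorrectedFARate:
    rate: float
    ci: tuple[float, float]
    n_pairs: int
    reps: int
    raw_rate: float


def corrected_false_alarm_rate(catch_saccade_latencies: np.ndarray,
                               n_catch: int,
                               go_onset_latencies: np.ndarray,
                               n_pairs: int | None = None,
                               reps: int = 1000,
                               seed: int = 0,
                               hit_window: tuple[float, float] = (0.05, 0.5),
                               catch_pool: str = "all",
                               catch_fraction: float = 0.4,
                               ) -> CorrectedFARate:
    """Resampling correction for the unequal-duration catch trials.

    Parameters
    ----------
    catch_saccade_latencies
        Saccade time relative to background onset for every catch trial that
        contains one (the remaining ``n_catch - len(...)`` catch trials had
        none and always score as correct rejections).
    n_catch
        Total number of catch trials.
    go_onset_latencies
        Reference-onset latency after background onset for every go trial.
    n_pairs
        Pairs per repetition; defaults to the expected catch count implied
        by the catch fraction and the go-trial total,
        ``round(n_go * f/(1-f))``.
    catch_pool
        ``"all"`` samples from every catch trial; ``"fa_only"`` restricts
        the draw to catch trials that contain a saccade (the literal
        reading), scaling the resulting rate by the raw saccade fraction.
    """
    fa_times = np.asarray(catch_saccade_latencies, dtype=np.float64)
    go_lat = np.asarray(go_onset_latencies, dtype=np.float64)
    if go_lat.size == 0:
        raise ValidationError("no go trials to pair against")
    if fa_times.size > n_catch:
        raise ValidationError("more saccade latencies than catch trials")
    if n_pairs is None:
        n_pairs = int(round(go_lat.size * catch_fraction / (1.0 - catch_fraction)))
    rng = seeded_rng(seed, "fa-correction")

    times = np.full(n_catch, np.nan)
    times[: fa_times.size] = fa_times
    raw_rate = fa_times.size / n_catch

    lo, hi = hit_window
    if catch_pool == "all":
        ci_draw = rng.integers(0, n_catch, size=(reps, n_pairs))
        t = times[ci_draw]
    elif catch_pool == "fa_only":
        if fa_times.size == 0:
            t = np.full((reps, n_pairs), np.nan)
        else:
            t = fa_times[rng.integers(0, fa_times.size, size=(reps, n_pairs))]
    else:
        raise ValueError(f"unknown catch_pool {catch_pool!r}")
    tg = go_lat[rng.integers(0, go_lat.size, size=(reps, n_pairs))]
    with np.errstate(invalid="ignore"):
        fa = (t >= tg + lo) & (t < tg + hi)
    counts = fa.sum(axis=1)
    rep_rates = counts / n_pairs
    if catch_pool == "fa_only":
        rep_rates = rep_rates * raw_rate  # only saccade-bearing trials drawn
        counts = np.round(rep_rates * n_pairs).astype(int)

    alpha = 0.05
    with np.errstate(invalid="ignore"):
        ci_lo = np.where(counts == 0, 0.0,
                         stats.beta.ppf(alpha / 2, counts, n_pairs - counts + 1))
        ci_hi = np.where(counts == n_pairs, 1.0,
                         stats.beta.ppf(1 - alpha / 2, counts + 1,
                                        n_pairs - counts))
    return CorrectedFARate(
        rate=float(rep_rates.mean()),
        ci=(float(np.mean(ci_lo)), float(np.mean(ci_hi))),
        n_pairs=n_pairs,
        reps=reps,
        raw_rate=raw_rate,
    )


def corrected_fa_from_trials(trials: TrialTable, reps: int = 1000,
                             seed: int = 0, **kw) -> CorrectedFARate:
    """Run the correction directly on a scored trial table."""
    df = trials.df
    catch = df[df["condition"] == "catch"]
    fa = catch[catch["outcome"] == "false_alarm"]
    fa_lat = (fa["response_time"] - fa["background_on"]).to_numpy(dtype=float)
    go = df[(df["condition"] != "catch")
            & df["outcome"].isin(["hit", "miss"])]
    go_lat = np.array([reference_onset(r) - r.background_on
                       for r in go.itertuples(index=False)])
    return corrected_false_alarm_rate(fa_lat, len(catch), go_lat,
                                      reps=reps, seed=seed, **kw)


def pairwise_rate_tests(tables: dict[str, tuple[int, int]],
                        family: tuple[tuple[str, str], ...] = FIG8B_CONTRASTS,
                        ) -> pd.DataFrame:
    """Yates-corrected 2x2 chi-squared per planned contrast, BH-adjusted
    across the family.

    ``tables`` maps condition -> (responders, total). Returns a DataFrame
    with columns ``a, b, chi2, p_raw, p_adj``; adjusted p's are monotone in
    the raw p's and never smaller.
    """
    rows = []
    for a, b in family:
        ka, na = tables[a]
        kb, nb = tables[b]
        tab = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
        expected = stats.contingency.expected_freq(tab)
        if expected.min() < 1:
            warnings.warn(f"contrast {a} vs {b}: expected cell below 1",
                          stacklevel=2)
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
        rows.append({"a": a, "b": b, "chi2": chi2, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df
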