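"""Signal-detection-theory sensitivity and bias with bootstrap inference.

d' = Z(HitRate) - Z(FalseAlarmRate) and c = -(Z(HitRate)+Z(FalseAlarmRate))/2,
with Z the inverse standard-normal CDF. Confidence intervals come from
resampling the per-trial 0/1 outcome vectors with replacement (10,000
replications; 5th/95th percentiles); contrast p-values are the proportion of
replicate differences falling on the opposite side of zero from the observed
difference, floored at 1/B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from ..core.rng import seeded_rng

__all__ = ["SDTResult", "SDTContrast", "dprime_criterion", "bootstrap_sdt",
           "bootstrap_sdt_contrast"]


@dataclass
class SDTResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    dprime_ci: tuple[float, float]
    criterion_ci: tuple[float, float]
    n_signal: int
    n_noise: int
    b: int


@dataclass
class SDTContrast:
    """Difference (B - A) in d' and c between two condition pairs."""

    delta_dprime: float
    delta_criterion: float
    p_dprime: float
    p_criterion: float
    b: int


def dprime_criterion(hit_rate: float, fa_rate: float,
                     correction_n: tuple[int, int] | None = None,
                     ) -> tuple[float, float]:
    """Sensitivity and response bias from a (hit rate, false-alarm rate) pair.

    Rates must lie strictly inside (0, 1); pass ``correction_n=(n_signal,
    n_noise)`` to clamp extreme rates to the conventional 1/(2N) bounds.
    """
    if correction_n is not None:
        ns, nn = correction_n
        hit_rate = min(max(hit_rate, 0.5 / ns), 1.0 - 0.5 / ns)
        fa_rate = min(max(fa_rate, 0.5 / nn), 1.0 - 0.5 / nn)
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError(
            "rates must lie strictly in (0, 1); pass correction_n=(n_signal, "
            "n_noise) to apply the 1/(2N) boundary correction")
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return float(zh - zf), float(-0.5 * (zh + zf))


def _replicate_rates(k: int, n: int, b: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Rates from resampling an n-long 0/1 vector (k ones) with replacement:
    Binomial(n, k/n)/n, clamped away from {0, 1} to keep Z finite."""
    rates = rng.binomial(n, k / n, size=b) / n
    return np.clip(rates, 0.5 / n, 1.0 - 0.5 / n)


def bootstrap_sdt(hits: int, misses: int, false_alarms: int,
                  correct_rejections: int, b: int = 10000, seed: int = 0,
                  percentiles: tuple[float, float] = (5.0, 95.0),
                  stream: str = "sdt") -> SDTResult:
    """d'/c with bootstrap confidence intervals for one condition pair."""
    if b < 100:
        raise ValueError("need at least 100 bootstrap replications")
    for name, v in (("hits", hits), ("misses", misses),
                    ("false_alarms", false_alarms),
                    ("correct_rejections", correct_rejections)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    ns, nn = hits + misses, false_alarms + correct_rejections
    d, c = dprime_criterion(hits / ns, false_alarms / nn)
    rng = seeded_rng(seed, stream)
    h = _replicate_rates(hits, ns, b, rng)
    f = _replicate_rates(false_alarms, nn, b, rng)
    zh, zf = norm.ppf(h), norm.ppf(f)
    d_rep, c_rep = zh - zf, -0.5 * (zh + zf)
    lo, hi = percentiles
    return SDTResult(
        hit_rate=hits / ns, fa_rate=false_alarms / nn,
        dprime=d, criterion=c,
        dprime_ci=(float(np.percentile(d_rep, lo)),
                   float(np.percentile(d_rep, hi))),
        criterion_ci=(float(np.percentile(c_rep, lo)),
                      float(np.percentile(c_rep, hi))),
        n_signal=ns, n_noise=nn, b=b,
    )


def bootstrap_sdt_contrast(pair_a: tuple[int, int, int, int],
                           pair_b: tuple[int, int, int, int],
                           b: int = 10000, seed: int = 0,
                           method: str = "sign") -> SDTContrast:
    """Bootstrap test of the d' and c differences between two condition
    pairs, each given as (hits, misses, false_alarms, correct_rejections).

    ``method="sign"`` (default): p = proportion of replicate differences on
    the opposite side of 0 from the observed difference, floored at 1/b.
    ``method="literal"``: p = proportion of replicate differences >= the
    observed difference (~0.5 for a self-contrast by construction).
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replications")
    rng = seeded_rng(seed, "sdt-contrast")

    def reps(counts: tuple[int, int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        hits, misses, fas, crs = counts
        ns, nn = hits + misses, fas + crs
        h = _replicate_rates(hits, ns, b, rng)
        f = _replicate_rates(fas, nn, b, rng)
        zh, zf = norm.ppf(h), norm.ppf(f)
        return zh - zf, -0.5 * (zh + zf)

    da, ca = reps(pair_a)
    db, cb = reps(pair_b)

    def observed(counts):
        hits, misses, fas, crs = counts
        return dprime_criterion(hits / (hits + misses), fas / (fas + crs))

    d_obs = observed(pair_b)[0] - observed(pair_a)[0]
    c_obs = observed(pair_b)[1] - observed(pair_a)[1]
    d_diff, c_diff = db - da, cb - ca

    def pval(diff: np.ndarray, obs: float) -> float:
        if method == "sign":
            opposite = diff <= 0 if obs > 0 else diff >= 0
            return max(float(np.mean(opposite)), 1.0 / b)
        if method == "literal":
            return max(float(np.mean(diff >= obs)), 1.0 / b)
        raise ValueError(f"unknown method {method!r}")

    return SDTContrast(
        delta_dprime=d_obs, delta_criterion=c_obs,
        p_dprime=pval(d_diff, d_obs),
        p_criterion=pval(c_diff, c_obs),
        b=b,
    )
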