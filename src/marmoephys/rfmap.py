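"""Receptive-field mapping from wedge/annulus stimulus responses.

Epochs of -100..+180 ms around each stimulus onset are kept only when the
eye stayed inside the fixation window throughout; epochs whose MUA standard
deviation exceeds 10x the median across epochs are rejected as noise. A site
counts as modulated when at least three different wedges AND three different
annuli evoke responses significantly above the -100..0 ms baseline
(one-tailed paired t-test, p < 0.01). The map over (eccentricity, polar
angle) is the product of the min-max-normalized marginal response profiles,
renormalized to [0, 1], with the outline drawn at the 0.2 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core.config import AnalysisConfig
from .core.types import EyeTrace, ValidationError
from .preprocess import MUASeries

__all__ = [
    "WedgeStim",
    "AnnulusStim",
    "RFEpochs",
    "RFMap",
    "epoch_rf",
    "reject_noise_epochs",
    "classify_rf_modulation",
    "build_rf_map",
]


@dataclass(frozen=True)
class WedgeStim:
    """Angular sector covering all eccentricities. Angles in degrees CCW
    from +x; the sector spans ``[angle_lo, angle_hi)`` (may wrap)."""

    stim_id: str
    angle_lo: float
    angle_hi: float

    def contains_angle(self, theta_deg: np.ndarray) -> np.ndarray:
        lo = self.angle_lo % 360.0
        hi = self.angle_hi % 360.0
        th = np.asarray(theta_deg) % 360.0
        if lo <= hi:
            return (th >= lo) & (th < hi)
        return (th >= lo) | (th < hi)


@dataclass(frozen=True)
class AnnulusStim:
    """Eccentricity band ``[ecc_lo, ecc_hi)`` covering all polar angles."""

    stim_id: str
    ecc_lo: float
    ecc_hi: float

    def contains_ecc(self, ecc_deg: np.ndarray) -> np.ndarray:
        e = np.asarray(ecc_deg)
        return (e >= self.ecc_lo) & (e < self.ecc_hi)


@dataclass
class RFEpochs:
    """Per-epoch MUA for one site: ``values`` is (epochs, time) at 1 kHz."""

    values: np.ndarray
    stim_ids: np.ndarray  # str per epoch
    rate: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.stim_ids = np.asarray(self.stim_ids)
        if self.values.shape[0] != self.stim_ids.size:
            raise ValidationError("stim_ids must match epoch count")

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.window[0] + np.arange(self.values.shape[1]) / self.rate
        return (t >= window[0]) & (t < window[1])


@dataclass
class RFMap:
    map: np.ndarray  # (n_ecc, n_angle), values in [0, 1]
    ecc_centers: np.ndarray
    angle_centers: np.ndarray
    outline: np.ndarray  # bool mask at the truncation level
    centroid: tuple[float, float]  # (eccentricity deg, polar angle deg)
    modulated: bool
    wedge_responses: dict[str, tuple[float, float]] = field(default_factory=dict)
    annulus_responses: dict[str, tuple[float, float]] = field(default_factory=dict)


def epoch_rf(mua: MUASeries, stim_onsets: np.ndarray, stim_ids: np.ndarray,
             eye: EyeTrace | None = None,
             fixation_center: tuple[float, float] = (0.0, 0.0),
             fixation_radius: float = 1.4,
             channel: int = 0,
             window: tuple[float, float] = (-0.1, 0.18)) -> RFEpochs:
    """Cut fixation-controlled epochs around stimulus onsets for one site."""
    stim_onsets = np.asarray(stim_onsets, dtype=np.float64)
    stim_ids = np.asarray(stim_ids)
    if stim_onsets.size == 0:
        raise ValidationError("empty stimulus set")
    n_win = int(round((window[1] - window[0]) * mua.rate))
    keep_vals, keep_ids = [], []
    for onset, sid in zip(stim_onsets, stim_ids):
        s = int(round((onset + window[0] - mua.t0) * mua.rate))
        if s < 0 or s + n_win > mua.values.shape[1]:
            continue
        if eye is not None:
            e0 = int(round((onset + window[0] - eye.t[0]) * eye.rate))
            e1 = e0 + int(round((window[1] - window[0]) * eye.rate))
            e0, e1 = max(e0, 0), min(e1, eye.t.size)
            dx = eye.x[e0:e1] - fixation_center[0]
            dy = eye.y[e0:e1] - fixation_center[1]
            if np.any(np.hypot(dx, dy) > fixation_radius):
                continue
        keep_vals.append(mua.values[channel, s: s + n_win])
        keep_ids.append(sid)
    if not keep_vals:
        raise ValidationError("no eligible epochs after fixation control")
    return RFEpochs(np.stack(keep_vals), np.asarray(keep_ids), mua.rate, window)


def reject_noise_epochs(epochs: RFEpochs, std_factor: float = 10.0) -> RFEpochs:
    """Drop epochs whose across-time STD exceeds ``std_factor`` x the median
    STD over all epochs. Idempotent in the homogeneous case."""
    stds = epochs.values.std(axis=1, ddof=0)
    keep = stds <= std_factor * np.median(stds)
    return RFEpochs(epochs.values[keep], epochs.stim_ids[keep],
                    epochs.rate, epochs.window)


def classify_rf_modulation(epochs: RFEpochs,
                           stimuli: list[WedgeStim | AnnulusStim],
                           config: AnalysisConfig | None = None,
                           response_window: tuple[float, float] = (0.0, 0.18),
                           ) -> tuple[bool, dict[str, float]]:
    """Per-stimulus one-tailed paired t-test (response vs baseline mean,
    across that stimulus's epochs). Modulated iff >= 3 wedges and >= 3
    annuli are significant at the configured alpha.
    Returns ``(modulated, {stim_id: p})``.
    """
    cfg = config or AnalysisConfig()
    base_mask = epochs.window_mask(cfg.rf_baseline)
    resp_mask = epochs.window_mask(response_window)
    p_by_stim: dict[str, float] = {}
    for stim in stimuli:
        sel = epochs.stim_ids == stim.stim_id
        n = int(np.count_nonzero(sel))
        if n < 2:
            warnings.warn(f"stimulus {stim.stim_id}: fewer than 2 epochs, skipped",
                          stacklevel=2)
            continue
        resp = epochs.values[sel][:, resp_mask].mean(axis=1)
        base = epochs.values[sel][:, base_mask].mean(axis=1)
        if np.allclose(resp, base):
            p_by_stim[stim.stim_id] = 1.0
            continue
        p_by_stim[stim.stim_id] = stats.ttest_rel(
            resp, base, alternative="greater").pvalue
    n_wedge = sum(1 for s in stimuli if isinstance(s, WedgeStim)
                  and p_by_stim.get(s.stim_id, 1.0) < cfg.rf_t_alpha)
    n_ann = sum(1 for s in stimuli if isinstance(s, AnnulusStim)
                and p_by_stim.get(s.stim_id, 1.0) < cfg.rf_t_alpha)
    modulated = (n_wedge >= cfg.rf_min_significant
                 and n_ann >= cfg.rf_min_significant)
    return modulated, p_by_stim


def _normalize(profile: np.ndarray) -> np.ndarray:
    span = profile.max() - profile.min()
    if span == 0:
        return np.zeros_like(profile)
    return (profile - profile.min()) / span


def build_rf_map(epochs: RFEpochs,
                 stimuli: list[WedgeStim | AnnulusStim],
                 config: AnalysisConfig | None = None,
                 response_window: tuple[float, float] = (0.0, 0.18),
                 n_angle: int = 24, n_ecc: int = 12,
                 ecc_max: float | None = None) -> RFMap:
    """Combine wedge and annulus response profiles into a normalized map.

    The angle profile holds, per angular bin, the mean baseline-subtracted
    response of the wedges covering it; likewise the eccentricity profile for
    annuli. map = normalized(angle profile) x normalized(ecc profile), then
    min-max normalized; outline at the configured truncation level; centroid
    is the response-weighted mean over the supra-threshold region (circular
    mean for the angle).
    """
    cfg = config or AnalysisConfig()
    wedges = [s for s in stimuli if isinstance(s, WedgeStim)]
    annuli = [s for s in stimuli if isinstance(s, AnnulusStim)]
    if not wedges or not annuli:
        raise ValidationError("need both wedge and annulus stimuli")
    if ecc_max is None:
        ecc_max = max(a.ecc_hi for a in annuli)

    base_mask = epochs.window_mask(cfg.rf_baseline)
    resp_mask = epochs.window_mask(response_window)

    def mean_sem(sid: str) -> tuple[float, float]:
        sel = epochs.stim_ids == sid
        if not np.any(sel):
            return 0.0, 0.0
        vals = (epochs.values[sel][:, resp_mask].mean(axis=1)
                - epochs.values[sel][:, base_mask].mean(axis=1))
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        return float(vals.mean()), float(sem)

    wedge_resp = {w.stim_id: mean_sem(w.stim_id) for w in wedges}
    ann_resp = {a.stim_id: mean_sem(a.stim_id) for a in annuli}

    angle_centers = (np.arange(n_angle) + 0.5) * 360.0 / n_angle
    ecc_centers = (np.arange(n_ecc) + 0.5) * ecc_max / n_ecc

    angle_prof = np.zeros(n_angle)
    for i, th in enumerate(angle_centers):
        vals = [max(wedge_resp[w.stim_id][0], 0.0) for w in wedges
                if w.contains_angle(np.array([th]))[0]]
        angle_prof[i] = np.mean(vals) if vals else 0.0
    ecc_prof = np.zeros(n_ecc)
    for i, e in enumerate(ecc_centers):
        vals = [max(ann_resp[a.stim_id][0], 0.0) for a in annuli
                if a.contains_ecc(np.array([e]))[0]]
        ecc_prof[i] = np.mean(vals) if vals else 0.0

    rf = np.outer(_normalize(ecc_prof), _normalize(angle_prof))
    rf = _normalize(rf)
    outline = rf > cfg.rf_outline_level

    if outline.any():
        w = rf * outline
        wsum = w.sum()
        ecc_c = float((w.sum(axis=1) @ ecc_centers) / wsum)
        ang_w = w.sum(axis=0)
        th = np.deg2rad(angle_centers)
        ang_c = float(np.rad2deg(np.arctan2((ang_w * np.sin(th)).sum(),
                                            (ang_w * np.cos(th)).sum())) % 360.0)
    else:
        ecc_c, ang_c = float("nan"), float("nan")

    modulated, _ = classify_rf_modulation(epochs, stimuli, cfg, response_window)
    return RFMap(rf, ecc_centers, angle_centers, outline, (ecc_c, ang_c),
                 modulated, wedge_resp, ann_resp)
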