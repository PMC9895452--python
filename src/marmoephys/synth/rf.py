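"""Synthetic receptive-field mapping responses.

Per-stimulus epoched MUA whose response amplitude is proportional to the
overlap between the stimulus region (wedge sector or annulus band) and a
Gaussian ground-truth RF, plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core.rng import seeded_rng
from ..core.types import ValidationError
from ..rfmap import AnnulusStim, RFEpochs, WedgeStim

__all__ = ["TrueRF", "simulate_rf_responses", "standard_stimulus_set"]


@dataclass(frozen=True)
class TrueRF:
    ecc: float  # degrees
    angle: float  # degrees CCW from +x
    sigma_ecc: float = 1.5
    sigma_angle: float = 20.0  # degrees


def standard_stimulus_set(n_wedges: int = 8, n_annuli: int = 6,
                          ecc_max: float = 12.0,
                          ) -> list[WedgeStim | AnnulusStim]:
    """Wedges tiling the full circle and annuli tiling eccentricity."""
    stims: list[WedgeStim | AnnulusStim] = []
    for i in range(n_wedges):
        lo = i * 360.0 / n_wedges
        stims.append(WedgeStim(f"wedge{i}", lo, lo + 360.0 / n_wedges))
    for i in range(n_annuli):
        lo = i * ecc_max / n_annuli
        stims.append(AnnulusStim(f"annulus{i}", lo, lo + ecc_max / n_annuli))
    return stims


def _overlap(stim: WedgeStim | AnnulusStim, rf: TrueRF,
             ecc_max: float, n_grid: int = 60) -> float:
    """Mean RF density over the stimulus region (polar grid approximation)."""
    ecc = np.linspace(0.0, ecc_max, n_grid)
    ang = np.linspace(0.0, 360.0, n_grid, endpoint=False)
    E, A = np.meshgrid(ecc, ang, indexing="ij")
    d_ang = (A - rf.angle + 180.0) % 360.0 - 180.0
    density = np.exp(-0.5 * (((E - rf.ecc) / rf.sigma_ecc) ** 2
                             + (d_ang / rf.sigma_angle) ** 2))
    if isinstance(stim, WedgeStim):
        mask = stim.contains_angle(A)
    else:
        mask = stim.contains_ecc(E)
    return float(density[mask].mean()) if mask.any() else 0.0


def simulate_rf_responses(stimuli: list[WedgeStim | AnnulusStim],
                          rf: TrueRF | None,
                          n_epochs_per_stim: int = 20,
                          response_gain: float = 5.0,
                          baseline_level: float = 1.0,
                          noise_sigma: float = 0.2,
                          seed: int = 0,
                          rate: float = 1000.0,
                          window: tuple[float, float] = (-0.1, 0.18),
                          ecc_max: float | None = None,
                          ) -> tuple[RFEpochs, TrueRF | None]:
    """Epoched MUA per stimulus with amplitude ~ stimulus/RF overlap.

    ``rf=None`` simulates an unresponsive (flat) site. The response occupies
    the post-onset part of each epoch with a 30 ms onset ramp.
    """
    if not stimuli:
        raise ValidationError("empty stimulus set")
    if ecc_max is None:
        anns = [s for s in stimuli if isinstance(s, AnnulusStim)]
        ecc_max = max((a.ecc_hi for a in anns), default=12.0)
    rng = seeded_rng(seed, "rf")
    n_time = int(round((window[1] - window[0]) * rate))
    t = window[0] + np.arange(n_time) / rate
    onset_ramp = np.clip(t / 0.03, 0.0, 1.0) * (t >= 0)

    values, ids = [], []
    for stim in stimuli:
        amp = response_gain * _overlap(stim, rf, ecc_max) if rf is not None \
            else 0.0
        for _ in range(n_epochs_per_stim):
            trace = baseline_level + amp * onset_ramp
            if noise_sigma > 0:
                trace = trace + noise_sigma * rng.standard_normal(n_time)
            values.append(np.clip(trace, 0.0, None))
            ids.append(stim.stim_id)
    return RFEpochs(np.stack(values), np.asarray(ids), rate, window), rf
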