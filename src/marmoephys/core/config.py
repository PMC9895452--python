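"""Analysis configuration: every pipeline threshold/window with its default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All numeric constants of the pipeline, overridable from YAML.

    Defaults are the values used throughout: modulation z threshold 3 with
    KS / rank-sum alpha 0.05, ISI-violation limit 2.5% below 1.5 ms, template
    correlation 0.95, spatial spread < 5 channels, RF epochs of -100..+180 ms
    with a one-tailed paired t-test at alpha 0.01, saccade velocity threshold
    50 deg/s after 3 ms-sigma smoothing, hit window 50-500 ms, catch fixation
    800 ms, 10000 bootstrap replications and 1000 false-alarm resampling
    repetitions.
    """

    # modulation statistics
    z_threshold: float = 3.0
    ks_alpha: float = 0.05
    ranksum_alpha: float = 0.05
    visual_baseline: tuple[float, float] = (-0.25, 0.0)
    visual_stim: tuple[float, float] = (0.0, 0.65)
    opto_mua_baseline: tuple[float, float] = (-0.025, 0.0)
    opto_mua_stim: tuple[float, float] = (0.0, 0.025)
    opto_sua_baseline: tuple[float, float] = (-0.25, 0.0)
    opto_sua_stim: tuple[float, float] = (0.0, 0.25)

    # spike-cluster curation
    isi_violation_limit: float = 0.025
    isi_refractory_s: float = 0.0015
    template_r_threshold: float = 0.95
    spread_channel_limit: int = 5
    waveform_trim_fraction: float = 0.05
    acg_bin_s: float = 0.00033
    acg_span_s: float = 0.05

    # receptive-field mapping
    rf_epoch: tuple[float, float] = (-0.1, 0.18)
    rf_baseline: tuple[float, float] = (-0.1, 0.0)
    rf_noise_std_factor: float = 10.0
    rf_t_alpha: float = 0.01
    rf_min_significant: int = 3
    rf_outline_level: float = 0.2

    # saccades / behavior
    saccade_smooth_sigma_s: float = 0.003
    saccade_velocity_threshold: float = 50.0  # deg/s
    saccade_merge_gap_s: float = 0.010
    saccade_endpoint_window_s: float = 0.025
    hit_window: tuple[float, float] = (0.05, 0.5)
    catch_fixation_s: float = 0.8
    catch_fraction: float = 0.4

    # resampling / bootstrap
    fa_resampling_reps: int = 1000
    bootstrap_b: int = 10000
    ci_percentiles: tuple[float, float] = (5.0, 95.0)

    # laser synthesis
    laser_taper_s: float = 0.005  # trough-to-peak edge taper

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "z_threshold",
            "isi_refractory_s",
            "template_r_threshold",
            "spread_channel_limit",
            "rf_noise_std_factor",
            "saccade_velocity_threshold",
            "fa_resampling_reps",
            "bootstrap_b",
            "laser_taper_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("ks_alpha", "ranksum_alpha", "rf_t_alpha",
                     "isi_violation_limit", "catch_fraction",
                     "waveform_trim_fraction", "rf_outline_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
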