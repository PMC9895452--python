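"""Shared data model for recordings, trials, eye traces and spike clusters.

All times are seconds, double precision, session-relative (t = 0 at recording
start). Analysis windows are half-open ``[start, end)``. Voltages are µV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "OUTCOMES",
    "ChannelInfo",
    "RecordingBlock",
    "EyeTrace",
    "SpikeCluster",
    "TrialTable",
    "SessionBundle",
    "ValidationError",
    "FormatError",
    "validate_trial_table",
]

#: Closed set of detection-task condition labels.
CONDITIONS = (
    "high",
    "high+opto",
    "low",
    "low+opto",
    "opto_only",
    "sham",
    "catch",
)

#: Trial outcomes assigned by the scoring stage ("" = unscored).
OUTCOMES = (
    "hit",
    "miss",
    "false_alarm",
    "correct_rejection",
    "early",
    "excluded",
    "",
)

#: Go conditions whose reference onset is the visual target.
VISUAL_CONDITIONS = ("high", "high+opto", "low", "low+opto")
#: Go conditions whose reference onset is the laser.
LASER_ONLY_CONDITIONS = ("opto_only", "sham")

TRIAL_COLUMNS = (
    "trial_id",
    "condition",
    "fixation_on",
    "background_on",
    "target_on",
    "laser_on",
    "response_time",
    "outcome",
)


class ValidationError(ValueError):
    """Raised when a data structure violates its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed or incomplete."""


@dataclass(frozen=True)
class ChannelInfo:
    """Probe-geometry entry for one channel."""

    shank: int
    index: int  # within-shank site index, 0-based
    depth_um: float


@dataclass
class RecordingBlock:
    """Multichannel voltage trace with sampling rate and probe geometry.

    Parameters
    ----------
    samples
        ``(n_channels, n_time)`` float array, µV.
    rate
        Sampling rate in Hz.
    channel_map
        One :class:`ChannelInfo` per channel, same order as rows of
        ``samples``.
    t0
        Session-relative time of the first sample, seconds.
    """

    samples: np.ndarray
    rate: float
    channel_map: list[ChannelInfo]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels x time)")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")
        if len(self.channel_map) != self.samples.shape[0]:
            raise ValidationError(
                f"channel_map length {len(self.channel_map)} does not match "
                f"channel count {self.samples.shape[0]}"
            )
        for shank in {c.shank for c in self.channel_map}:
            idx = [c.index for c in self.channel_map if c.shank == shank]
            if len(idx) != len(set(idx)):
                raise ValidationError(f"duplicate within-shank index on shank {shank}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def shank_channels(self, shank: int) -> np.ndarray:
        """Row indices of the channels belonging to ``shank``."""
        return np.array(
            [i for i, c in enumerate(self.channel_map) if c.shank == shank],
            dtype=np.intp,
        )

    @property
    def shanks(self) -> list[int]:
        return sorted({c.shank for c in self.channel_map})


@dataclass
class EyeTrace:
    """Gaze position in degrees of visual angle at a fixed rate.

    +x is rightward, +y is upward; polar angle is counterclockwise from +x.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float
    blink: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.blink is None:
            self.blink = np.zeros(self.t.shape, dtype=bool)
        else:
            self.blink = np.asarray(self.blink, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.blink.size == n):
            raise ValidationError("t, x, y, blink must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-9):
                raise ValidationError("eye trace is not uniformly sampled at rate")


@dataclass
class SpikeCluster:
    """One sorted unit: spike times plus per-spike waveform snippets."""

    unit_id: int
    spike_times: np.ndarray
    snippets: np.ndarray | None = None  # (spikes, channels, samples), µV
    mean_waveform: np.ndarray | None = None  # (channels, samples)
    peak_channel: int | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times not sorted")
        if self.snippets is not None:
            self.snippets = np.asarray(self.snippets, dtype=np.float64)
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=np.float64)
            if self.peak_channel is None:
                amp = np.ptp(self.mean_waveform, axis=1)
                self.peak_channel = int(np.argmax(amp))

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class TrialTable:
    """Per-trial condition labels, event times and outcomes.

    Backed by a :class:`pandas.DataFrame` with the fixed column set
    ``TRIAL_COLUMNS``; absent event times are NaN, unscored outcomes are "".
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"trial table missing columns: {missing}")
        self.df = self.df.loc[:, list(TRIAL_COLUMNS)].reset_index(drop=True)
        self.df["outcome"] = self.df["outcome"].fillna("").astype(str)
        self.df["condition"] = self.df["condition"].astype(str)
        for col in TRIAL_COLUMNS[2:7]:
            self.df[col] = pd.to_numeric(self.df[col], errors="coerce")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_exact=False, atol=1e-9)
        except AssertionError:
            return False
        return True


def validate_trial_table(table: TrialTable) -> TrialTable:
    """Check condition labels, event-time ordering and catch-trial structure.

    Returns the table unchanged on success.

    Raises
    ------
    ValidationError
        Unknown condition label, nonmonotonic event times (citing the trial
        id), a catch trial carrying a target onset, or a response before the
        first event.
    """
    df = table.df
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels: {sorted(bad)}")
    bad_out = set(df["outcome"]) - set(OUTCOMES)
    if bad_out:
        raise ValidationError(f"unknown outcome labels: {sorted(bad_out)}")
    event_cols = ["fixation_on", "background_on", "target_on", "laser_on"]
    for row in df.itertuples(index=False):
        times = [getattr(row, c) for c in event_cols]
        present = [t for t in times if not np.isnan(t)]
        # target and laser onsets may coincide (paired stimulation); all
        # other event times must strictly increase
        paired = (not np.isnan(row.target_on)
                  and row.target_on == row.laser_on)
        ok = all(
            (b > a) or (paired and b == a == row.target_on)
            for a, b in zip(present, present[1:])
        )
        if not ok:
            raise ValidationError(
                f"trial {row.trial_id}: event times not strictly increasing"
            )
        if row.condition == "catch" and not np.isnan(row.target_on):
            raise ValidationError(
                f"trial {row.trial_id}: catch trials have no target"
            )
        if not np.isnan(row.response_time) and present:
            if row.response_time < present[0]:
                raise ValidationError(
                    f"trial {row.trial_id}: response before first event"
                )
    return table


@dataclass
class SessionBundle:
    """Container for the artifacts of one session (any subset may be set)."""

    recording: RecordingBlock | None = None
    trials: TrialTable | None = None
    eye: EyeTrace | None = None
    clusters: list[SpikeCluster] = field(default_factory=list)

    def is_empty(self) -> bool:
        return (
            self.recording is None
            and self.trials is None
            and self.eye is None
            and not self.clusters
        )
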