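"""Core data containers shared across modules.

Kept separate so the synthetic generator, preprocessing and I/O layers can
all produce/consume the same objects without circular imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 13-channel scalp montage (10–20 positions) used throughout.
CHANNELS_13 = ["Fpz", "F3", "Fz", "F4", "T3", "C3", "Cz", "C4", "T4", "P3", "Pz", "P4", "Oz"]

#: Sleep-stage alphabet of 20-s scoring epochs.
STAGES = ("W", "N1", "N2", "N3", "R")

EPOCH_LENGTH_S = 20.0


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG in microvolts.

    ``data`` is (n_channels, n_samples); ``reference`` records whether the
    signal is still against the online reference electrode (Fpz) or has been
    re-referenced to the common average.
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    reference: str = "Fpz-online"
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def good_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, ch in enumerate(self.channel_labels) if ch not in self.bad_channels],
            dtype=int,
        )


@dataclass
class Hypnogram:
    """Sleep stages scored on consecutive 20-s epochs.

    Epochs are half-open intervals ``[k*20, (k+1)*20)`` seconds.
    """

    stages: list[str]
    epoch_length: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        if self.epoch_length != EPOCH_LENGTH_S:
            raise ValueError("scoring epochs are fixed at 20 s")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_length

    def stage_at(self, t: float) -> str | None:
        """Stage of the epoch containing time ``t`` (s), or None if unscored."""
        if t < 0:
            return None
        k = int(t // self.epoch_length)
        if k >= len(self.stages):
            return None
        return self.stages[k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.stages)),
                "onset_s": np.arange(len(self.stages)) * self.epoch_length,
                "stage": self.stages,
            }
        )


@dataclass
class EpochSet:
    """Epoched trials with per-trial metadata and rejection bookkeeping.

    ``data`` is (n_trials, n_channels, n_times); ``events`` carries one row
    per trial (onset_sample, stimulus_id, condition, roughness, pitch, ...).
    Rejected trials stay in place (kept=False) so that
    kept + rejected always equals the number of events.
    """

    data: np.ndarray
    times: np.ndarray  # s relative to onset
    rate: float
    channel_labels: list[str]
    events: pd.DataFrame
    window: tuple[float, float]
    vigilance: np.ndarray | None = None  # per-trial {wake, NREM, REM} or None
    kept: np.ndarray | None = None
    reject_reason: np.ndarray | None = None
    qc_fail: bool = False

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if self.kept is None:
            self.kept = np.ones(n, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.array([""] * n, dtype=object)
        if self.vigilance is None:
            self.vigilance = np.array([None] * n, dtype=object)
        if not (self.window[0] <= 0 <= self.window[1]):
            raise ValueError("epoch window must contain t=0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def reject(self, idx, reason: str) -> None:
        idx = np.atleast_1d(idx)
        for i in idx:
            if not self.kept[i]:
                continue
            self.kept[i] = False
            self.reject_reason[i] = reason

    def qc_counts(self) -> dict:
        reasons: dict[str, int] = {}
        for r in self.reject_reason[~self.kept]:
            reasons[r] = reasons.get(r, 0) + 1
        return {"n_events": self.n_trials, "n_kept": int(self.kept.sum()), "rejected": reasons}
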