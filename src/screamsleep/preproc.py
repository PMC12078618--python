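"""Preprocessing: filtering, re-referencing, epoching, labeling, QC.

Turns a continuous recording plus an event table and a hypnogram into a
labeled, artifact-screened :class:`~screamsleep.containers.EpochSet`.
Filtering operates on the continuous signal (before epoching); visual
artifact screening is replaced by deterministic amplitude/flatness
thresholds so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ContinuousEEG, EpochSet, Hypnogram

__all__ = [
    "FilterSpec",
    "bandpass",
    "rereference_common_average",
    "epoch",
    "label_epochs",
    "reject_artifacts",
    "baseline_correct",
    "MIN_KEPT_TRIALS",
]

#: Participants with fewer clean trials than this fail QC and are excluded.
MIN_KEPT_TRIALS = 100

#: Hypnogram stage -> vigilance label of a trial; None marks rejection.
STAGE_TO_VIGILANCE = {"W": "wake", "N2": "NREM", "N3": "NREM", "R": "REM", "N1": None}


@dataclass
class FilterSpec:
    """Butterworth band-pass description.

    ``order`` is the per-edge order (the convention of clinical EEG reports:
    a "1st-order" 0.1–30 Hz band-pass has one pole per band edge).
    ``zero_phase`` applies the filter forward and backward, doubling the
    effective order and cancelling group delay.
    """

    band: tuple[float, float]
    order: int = 1
    zero_phase: bool = False

    def validate(self, rate: float) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi < rate / 2):
            raise ValueError("need 0 <= low < high < Nyquist")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def bandpass(eeg: ContinuousEEG, spec: FilterSpec) -> ContinuousEEG:
    """Band-pass filter the continuous signal (second-order sections)."""
    spec.validate(eeg.rate)
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=eeg.rate, output="sos")
    poles = np.concatenate([np.roots(section[3:]) for section in sos])
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("unstable filter design (band too narrow for order and rate)")
    filt = sps.sosfiltfilt if spec.zero_phase else sps.sosfilt
    out = filt(sos, eeg.data, axis=1)
    return ContinuousEEG(
        data=np.asarray(out), rate=eeg.rate, channel_labels=list(eeg.channel_labels),
        reference=eeg.reference, bad_channels=list(eeg.bad_channels),
    )


def rereference_common_average(eeg: ContinuousEEG) -> ContinuousEEG:
    """Re-reference to the instantaneous mean of the good channels.

    Bad channels are excluded from the average but keep the subtraction,
    so re-applying the operation is a no-op (idempotence).
    """
    good = eeg.good_channel_indices()
    if good.size < 2:
        raise ValueError("common average reference needs at least 2 good channels")
    avg = eeg.data[good].mean(axis=0)
    return ContinuousEEG(
        data=eeg.data - avg[None, :], rate=eeg.rate,
        channel_labels=list(eeg.channel_labels), reference="common-average",
        bad_channels=list(eeg.bad_channels),
    )


def epoch(eeg: ContinuousEEG, events: pd.DataFrame, window: tuple[float, float]) -> EpochSet:
    """Cut trials of ``window`` seconds around each event onset.

    A trial of ``round((hi-lo)*rate)+1`` samples with the onset at index
    ``round(-lo*rate)``.  Events too close to the recording edge are kept in
    the set but flagged rejected (reason ``edge``), never dropped silently.
    """
    lo, hi = window
    rate = eeg.rate
    n_t = int(round((hi - lo) * rate)) + 1
    offset = int(round(lo * rate))
    onsets = events["onset_sample"].to_numpy(dtype=int)
    n_trials = onsets.size
    data = np.zeros((n_trials, eeg.data.shape[0], n_t))
    es = EpochSet(
        data=data,
        times=(np.arange(n_t) + offset) / rate,
        rate=rate,
        channel_labels=list(eeg.channel_labels),
        events=events.reset_index(drop=True),
        window=window,
    )
    for i, o in enumerate(onsets):
        start = o + offset
        stop = start + n_t
        if start < 0 or stop > eeg.n_samples:
            es.reject(i, "edge")
            continue
        data[i] = eeg.data[:, start:stop]
    return es


def label_epochs(epochs: EpochSet, hyp: Hypnogram) -> EpochSet:
    """Assign vigilance labels from the 20-s scoring epoch containing onset.

    W -> wake; N2/N3 -> NREM; R -> REM.  Onsets in N1 or beyond the scored
    record are flagged rejected (reasons ``N1`` / ``unscored``).
    """
    onsets = epochs.events["onset_sample"].to_numpy(dtype=int)
    for i, o in enumerate(onsets):
        stage = hyp.stage_at(o / epochs.rate)
        if stage is None:
            epochs.reject(i, "unscored")
            continue
        label = STAGE_TO_VIGILANCE[stage]
        if label is None:
            epochs.reject(i, "N1")
        else:
            epochs.vigilance[i] = label
    return epochs


def reject_artifacts(epochs: EpochSet, abs_threshold: float = 300.0,
                     flat_threshold: float = 1.0) -> EpochSet:
    """Amplitude/flatness screening (surrogate for visual inspection).

    A trial is rejected if any channel exceeds ±``abs_threshold`` µV
    (reason ``amplitude``) or if every channel's peak-to-peak falls below
    ``flat_threshold`` µV (reason ``flat``).  Sets ``epochs.qc_fail`` when
    fewer than :data:`MIN_KEPT_TRIALS` clean trials remain, mirroring the
    participant-exclusion rule for insufficient unartefacted trials.
    """
    if abs_threshold <= 0 or flat_threshold <= 0:
        raise ValueError("thresholds must be positive")
    for i in range(epochs.n_trials):
        if not epochs.kept[i]:
            continue
        trial = epochs.data[i]
        if np.abs(trial).max() > abs_threshold:
            epochs.reject(i, "amplitude")
        elif (trial.max(axis=1) - trial.min(axis=1)).max() < flat_threshold:
            epochs.reject(i, "flat")
    epochs.qc_fail = bool(epochs.kept.sum() < MIN_KEPT_TRIALS)
    return epochs


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a pre-stimulus window."""
    lo, hi = window
    if hi > 0 or lo < epochs.window[0]:
        raise ValueError("baseline window must lie within the epoch, before onset")
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    epochs.data -= epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs
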