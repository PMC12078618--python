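"""File I/O: EDF, event/hypnogram TSV, YAML configs, epoch containers, QC.

EDF writing is implemented here directly (the format is a fixed-layout
ASCII header plus little-endian int16 samples); reading goes through
``mne`` when available, and the test suite round-trips one against the
other.  Everything else uses plain text formats (TSV, YAML, JSON) plus an
NPZ container with a JSON sidecar for epoched data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ContinuousEEG, EpochSet, Hypnogram

__all__ = [
    "write_edf",
    "read_edf",
    "write_events_tsv",
    "read_events_tsv",
    "write_hypnogram_tsv",
    "read_hypnogram_tsv",
    "save_config_yaml",
    "load_config_yaml",
    "save_epochs",
    "load_epochs",
    "write_qc_report",
]

_AUX_CHANNELS = ["EOG1", "EOG2", "EMG1", "EMG2"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, eeg: ContinuousEEG, patient: str = "X", recording: str = "synthetic",
              add_aux: bool = True) -> None:
    """Write continuous EEG (µV) as a 16-bit EDF file with 1-s data records.

    The EEG channels are followed by EOG/EMG placeholder channels (zeros),
    matching a standard polysomnography montage.  Requires an integer
    sampling rate; the signal is zero-padded to a whole number of records.
    """
    rate = int(round(eeg.rate))
    if abs(rate - eeg.rate) > 1e-9:
        raise ValueError("EDF records are 1 s; sampling rate must be an integer")
    data = eeg.data
    labels = list(eeg.channel_labels)
    if add_aux:
        data = np.vstack([data, np.zeros((len(_AUX_CHANNELS), data.shape[1]))])
        labels = labels + list(_AUX_CHANNELS)
    n_sig, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / rate))
    padded = np.zeros((n_sig, n_rec * rate))
    padded[:, :n_samp] = data

    phys_max = np.maximum(np.ceil(np.abs(padded).max(axis=1)), 1.0)
    digital = np.empty((n_sig, n_rec * rate), dtype="<i2")
    for i in range(n_sig):
        digital[i] = np.round(padded[i] / phys_max[i] * 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(patient, 80))
        fh.write(_pad(recording, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_sig + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_sig), 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in labels:
            fh.write(_pad("synthetic", 80))
        for _ in labels:
            fh.write(_pad("uV", 8))
        for pm in phys_max:
            fh.write(_pad(f"{-pm:.0f}", 8))
        for pm in phys_max:
            fh.write(_pad(f"{pm:.0f}", 8))
        for _ in labels:
            fh.write(_pad("-32768", 8))
        for _ in labels:
            fh.write(_pad("32767", 8))
        for _ in labels:
            fh.write(_pad("", 80))
        for _ in labels:
            fh.write(_pad(str(rate), 8))
        for _ in labels:
            fh.write(_pad("", 32))
        # data records: record-major, signal-major within record
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())


def read_edf(path, drop_aux: bool = True) -> ContinuousEEG:
    """Read an EDF file into a :class:`ContinuousEEG` (µV) via ``mne``."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne returns Volts
    if drop_aux:
        keep = [i for i, ch in enumerate(labels) if ch not in _AUX_CHANNELS]
        data = data[keep]
        labels = [labels[i] for i in keep]
    return ContinuousEEG(data=data, rate=float(raw.info["sfreq"]), channel_labels=labels)


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_hypnogram_tsv(path, hyp: Hypnogram) -> None:
    hyp.to_frame().to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    return Hypnogram(stages=list(df["stage"]))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config_yaml(path, config) -> None:
    """Serialize a config dataclass (or dict) to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config_yaml(path, cls=None):
    """Load a YAML config; with ``cls`` given, construct that dataclass."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if cls is None:
        return raw
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in raw.items() if k in fields}
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v) if k.endswith("_range") or k.endswith("window") else v
    return cls(**kwargs)


def save_epochs(path, epochs: EpochSet) -> None:
    """Epoch container: NPZ arrays plus a ``.json`` sidecar of metadata."""
    path = Path(path)
    np.savez(
        path,
        data=epochs.data,
        times=epochs.times,
        kept=epochs.kept,
    )
    sidecar = {
        "rate": epochs.rate,
        "window": list(epochs.window),
        "channel_labels": epochs.channel_labels,
        "events": _to_plain(epochs.events.to_dict(orient="list")),
        "vigilance": [v if v is None else str(v) for v in epochs.vigilance],
        "reject_reason": [str(r) for r in epochs.reject_reason],
        "qc_fail": epochs.qc_fail,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_epochs(path) -> EpochSet:
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    with open(path.with_suffix(".json")) as fh:
        side = json.load(fh)
    return EpochSet(
        data=npz["data"],
        times=npz["times"],
        rate=side["rate"],
        channel_labels=side["channel_labels"],
        events=pd.DataFrame(side["events"]),
        window=tuple(side["window"]),
        vigilance=np.array(side["vigilance"], dtype=object),
        kept=npz["kept"],
        reject_reason=np.array(side["reject_reason"], dtype=object),
        qc_fail=side["qc_fail"],
    )


def write_qc_report(path, qc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_to_plain(qc), fh, indent=1, sort_keys=True)
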