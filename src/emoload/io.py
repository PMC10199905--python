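"""Readers and writers: BrainVision, event/behavior/trait TSV, TFR HDF5."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def write_brainvision(data_uv: np.ndarray, srate: float, labels,
                      base_path, events=None) -> Path:
    """Write a BrainVision triplet (.vhdr/.eeg/.vmrk).

    ``data_uv`` is channels x samples in microvolts, stored multiplexed
    IEEE float32. ``events`` is an iterable of (onset_s, description) emitted
    as Stimulus markers. Returns the .vhdr path.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    data_uv = np.asarray(data_uv, dtype=np.float32)
    if data_uv.ndim != 2 or data_uv.shape[0] != len(labels):
        raise ValueError("data must be channels x samples matching labels")
    vhdr, eeg, vmrk = (base.with_suffix(s) for s in (".vhdr", ".eeg", ".vmrk"))

    data_uv.T.tofile(eeg)  # multiplexed: sample-major

    ch_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(labels))
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "\n[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={eeg.name}\n"
        f"MarkerFile={vmrk.name}\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={len(labels)}\n"
        f"SamplingInterval={1e6 / srate:.6f}\n"
        "\n[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n"
        "\n[Channel Infos]\n"
        f"{ch_lines}\n",
        encoding="utf-8")

    lines = ["Brain Vision Data Exchange Marker File, Version 1.0",
             "", "[Common Infos]", "Codepage=UTF-8",
             f"DataFile={eeg.name}", "", "[Marker Infos]",
             "Mk1=New Segment,,1,1,0,00000000000000000000"]
    for k, (onset_s, desc) in enumerate(events or [], start=2):
        smp = int(round(onset_s * srate)) + 1  # 1-based
        lines.append(f"Mk{k}=Stimulus,{desc},{smp},1,0")
    vmrk.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(vhdr_path):
    """Read a BrainVision recording via mne.

    Returns ``(data_uv channels x samples, srate, labels, events)`` with
    events as (onset_s, description) tuples.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne uses volts internally
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("Stimulus"):
            events.append((float(onset), desc.split("/", 1)[-1]))
    return data_uv, raw.info["sfreq"], tuple(raw.ch_names), events


def read_events_tsv(path) -> pd.DataFrame:
    """Event table with columns onset_s, emotion, load."""
    df = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "emotion", "load"} - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    return df


def read_behavior_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "condition", "trial", "n", "d", "correct"} - set(df.columns)
    if missing:
        raise ValueError(f"behavior TSV missing columns: {sorted(missing)}")
    return df


def read_traits_tsv(path) -> pd.DataFrame:
    from .synth import TRAIT_SCALES

    df = pd.read_csv(path, sep="\t")
    missing = set(TRAIT_SCALES) - set(df.columns)
    if missing:
        raise ValueError(f"traits TSV missing scales: {sorted(missing)}")
    return df


def save_tfr(stack, path) -> None:
    """Serialize a TFRStack to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=stack.values)
        f.create_dataset("mask", data=stack.mask)
        f.create_dataset("freqs", data=stack.freqs)
        f.create_dataset("times", data=stack.times)
        f.create_dataset("labels", data=np.array(stack.labels, dtype="S"))
        f.attrs["baseline_window"] = stack.baseline_window


def load_tfr(path):
    import h5py

    from .ersp import TFRStack

    with h5py.File(path, "r") as f:
        return TFRStack(
            values=f["values"][()],
            mask=f["mask"][()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            labels=tuple(x.decode() for x in f["labels"][()]),
            baseline_window=tuple(f.attrs["baseline_window"]),
        )
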