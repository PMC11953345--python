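"""Readers and writers for the pipeline's external formats.

Trial logs travel as CSV; multichannel series and trial sets as HDF5 with a
documented layout (datasets ``data``, ``sampling_rate``, ``time_zero``,
``condition``, ``compatibility``); EEG recordings can be imported from
BrainVision triplets (.vhdr/.vmrk/.eeg) via mne. A minimal BrainVision
*writer* is included for synthetic round-trip fixtures.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import TRIAL_LOG_COLUMNS, TrialSet


class FileFormatError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# trial logs (CSV)
# ---------------------------------------------------------------------------

def write_trial_log(log: pd.DataFrame, path) -> None:
    log[list(TRIAL_LOG_COLUMNS)].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    missing = set(TRIAL_LOG_COLUMNS) - set(log.columns)
    if missing:
        raise FileFormatError(f"trial log {path} missing columns {sorted(missing)}")
    log["correct"] = log["correct"].astype(bool)
    return log


# ---------------------------------------------------------------------------
# trial sets and series (HDF5)
# ---------------------------------------------------------------------------

def save_trialset(trials: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.attrs["sampling_rate"] = trials.sampling_rate
        f.attrs["time_zero"] = trials.time_zero
        f.attrs["subject_id"] = trials.subject_id
        str_dt = h5py.string_dtype()
        f.create_dataset("condition", data=[str(c) for c in trials.condition],
                         dtype=str_dt)
        f.create_dataset("compatibility",
                         data=[str(c) for c in trials.compatibility],
                         dtype=str_dt)
        if trials.channel_positions is not None:
            f.create_dataset("channel_positions",
                             data=trials.channel_positions)


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        pos = f["channel_positions"][()] if "channel_positions" in f else None
        return TrialSet(f["data"][()], float(f.attrs["sampling_rate"]),
                        int(f.attrs["time_zero"]),
                        f["condition"].asstr()[()],
                        f["compatibility"].asstr()[()],
                        str(f.attrs["subject_id"]), pos)


def save_series(series: np.ndarray, path, sampling_rate: float = 1.0,
                **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(series))
        f.attrs["sampling_rate"] = sampling_rate
        for k, v in attrs.items():
            f.attrs[k] = v


def load_series(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["data"][()]


# ---------------------------------------------------------------------------
# BrainVision import (and a minimal writer for synthetic fixtures)
# ---------------------------------------------------------------------------

def write_brainvision(data: np.ndarray, sfreq: float, path_stem,
                      ch_names=None, markers=()) -> Path:
    """Write a minimal BrainVision triplet (synthetic fixtures only).

    ``data`` is (n_channels, n_samples) in µV; binary format is multiplexed
    IEEE float32. ``markers`` is a sequence of (sample_index, description)
    stimulus markers. Returns the .vhdr path.
    """
    stem = Path(path_stem)
    data = np.asarray(data, np.float32)
    n_ch = data.shape[0]
    ch_names = ch_names or [f"Ch{i + 1}" for i in range(n_ch)]
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    with open(eeg, "wb") as f:
        f.write(data.T.tobytes())  # multiplexed
    lines = ["BrainVision Data Exchange Header File Version 1.0",
             "[Common Infos]",
             f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
             "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
             f"NumberOfChannels={n_ch}",
             f"SamplingInterval={1e6 / sfreq:g}",
             "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
             "[Channel Infos]"]
    lines += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(ch_names)]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    mlines = ["BrainVision Data Exchange Marker File, Version 1.0",
              "[Common Infos]", f"DataFile={eeg.name}", "[Marker Infos]",
              "Mk1=New Segment,,1,1,0"]
    for i, (sample, desc) in enumerate(markers, start=2):
        mlines.append(f"Mk{i}=Stimulus,{desc},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(header_path):
    """Read a BrainVision recording; returns (data µV (n_ch, n_samples),
    sfreq, ch_names, markers as (sample, description) list).

    Raises :class:`FileFormatError` on a missing/inconsistent triplet.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileFormatError(f"header file {header_path} not found")
    import mne
    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True,
                                          verbose="error")
    except Exception as e:
        raise FileFormatError(
            f"cannot parse BrainVision triplet {header_path}: {e}") from e
    data = raw.get_data() * 1e6  # mne stores volts
    markers = [(int(a["onset"] * raw.info["sfreq"]),
                a["description"].replace("Stimulus/", ""))
               for a in raw.annotations
               if not a["description"].startswith("New Segment")]
    return data, float(raw.info["sfreq"]), list(raw.ch_names), markers


def segment_epochs(data: np.ndarray, sfreq: float, markers,
                   marker_map: dict, tmin: float = -2.0, tmax: float = 2.0,
                   subject_id: str = "S01") -> TrialSet:
    """Cut a continuous recording into stimulus-locked epochs by marker code.

    ``marker_map`` maps marker descriptions to (condition, compatibility)
    pairs; unmapped markers are ignored. Epochs that would extend past the
    recording are dropped.
    """
    n_pre = int(round(-tmin * sfreq))
    n_post = int(round(tmax * sfreq))
    epochs, conds, compats = [], [], []
    n_samples = data.shape[1]
    for sample, desc in markers:
        if desc not in marker_map:
            continue
        if sample - n_pre < 0 or sample + n_post > n_samples:
            continue
        epochs.append(data[:, sample - n_pre:sample + n_post])
        c, k = marker_map[desc]
        conds.append(c)
        compats.append(k)
    if not epochs:
        raise ValueError("no epochs could be segmented")
    return TrialSet(np.stack(epochs), sfreq, n_pre, np.array(conds),
                    np.array(compats), subject_id)
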