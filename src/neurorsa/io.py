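"""File I/O: HDF5 recordings, BIDS-style TSVs, feature/RDM CSVs, JSON results.

Conventions: TSV files are tab-separated UTF-8 with a header row and "n/a"
for missing values; every RDM CSV gets a sidecar JSON recording the metric
and the upper-triangle ordering; all times are seconds and windows are
half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .rdm import RDM
from .signal import EpochSet
from .synthdata import FeatureSpace, GroundTruth, Recording

NA = "n/a"

_SIDE_CAR_NOTE = {
    "units": "seconds",
    "window_convention": "half-open [t0, t1) on the sample grid",
    "utv_order": "row-major upper triangle, i < j",
}


def write_recording(rec: Recording, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "recording.h5", "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=float(rec.fs))
    rec.events.to_csv(directory / "events.tsv", sep="\t", index=False,
                      na_rep=NA)
    rec.channels.to_csv(directory / "electrodes.tsv", sep="\t", index=False,
                        na_rep=NA)


def read_recording(directory: str | Path) -> Recording:
    directory = Path(directory)
    with h5py.File(directory / "recording.h5", "r") as f:
        signal = f["signal"][()]
        fs = float(f["fs"][()])
    events = read_events(directory / "events.tsv")
    channels = read_electrodes(directory / "electrodes.tsv")
    return Recording(signal=signal, fs=fs, events=events, channels=channels)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    for col in ("onset", "stimulus_id"):
        if col not in df.columns:
            raise ValueError(f"events file missing column {col!r}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    return df


def read_electrodes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    for col in ("name", "x", "y", "z", "roi"):
        if col not in df.columns:
            raise ValueError(f"electrodes file missing column {col!r}")
    return df


def write_feature_space(space: FeatureSpace, path: str | Path) -> None:
    df = pd.DataFrame(space.matrix, index=space.stimulus_id)
    df.index.name = "stimulus_id"
    df.to_csv(path)


def read_feature_space(path: str | Path, attribute: str) -> FeatureSpace:
    df = pd.read_csv(path, index_col="stimulus_id")
    return FeatureSpace(attribute=attribute, matrix=df.to_numpy(dtype=float),
                        stimulus_id=list(df.index.astype(str)))


def write_rdm(rdm: RDM, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(rdm.matrix, index=rdm.stimulus_id,
                      columns=rdm.stimulus_id)
    df.index.name = "stimulus_id"
    df.to_csv(path)
    sidecar = dict(_SIDE_CAR_NOTE, metric=rdm.metric)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True))


def read_rdm(path: str | Path) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, index_col="stimulus_id")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return RDM(matrix=df.to_numpy(dtype=float),
               stimulus_id=list(df.index.astype(str)),
               metric=sidecar["metric"])


def write_selection_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_selection_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA],
                     keep_default_na=True)
    for col in ("channel_id", "attribute", "p", "selected"):
        if col not in df.columns:
            raise ValueError(f"selection table missing column {col!r}")
    if df["selected"].dtype != bool:
        df["selected"] = df["selected"].astype(str).str.lower() == "true"
    if "reason" in df.columns:
        df["reason"] = df["reason"].fillna("")
    return df


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("envelope", data=epochs.envelope)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset("trial_stimulus",
                         data=np.asarray(epochs.trial_stimulus, dtype="S"))
        f.create_dataset("channel_id",
                         data=np.asarray(epochs.channel_id, dtype="S"))
        f.attrs["fs"] = float(epochs.fs)


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            envelope=f["envelope"][()],
            time=f["time"][()],
            trial_stimulus=f["trial_stimulus"][()].astype(str),
            fs=float(f.attrs["fs"]),
            channel_id=[c.decode() for c in f["channel_id"][()]],
        )


def write_ground_truth(gts: list[GroundTruth], path: str | Path) -> None:
    payload = []
    for gt in gts:
        d = dict(gt.__dict__)
        if d["weight_vector"] is not None:
            d["weight_vector"] = np.asarray(d["weight_vector"]).tolist()
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        if d.get("weight_vector") is not None:
            d["weight_vector"] = np.asarray(d["weight_vector"], dtype=float)
        out.append(GroundTruth(**d))
    return out


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes.to_csv(path, index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("neuron_id", "trial", "t_spike_s"):
        if col not in df.columns:
            raise ValueError(f"spike table missing column {col!r}")
    return df


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results_json(results: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(results), indent=2,
                                     sort_keys=True))
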