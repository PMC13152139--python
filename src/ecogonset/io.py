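"""File formats: HDF5 recordings/band power, CSV events and onset tables,
YAML configs.

HDF5 recording layout: datasets ``signal`` (channels x samples) and
``fs``; channel metadata under ``channels/<column>`` (strings UTF-8).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import BandPower, BandSpec, GloveTrace, GroundTruth, Recording, TrialSet
from .synth import SynthConfig

_CHANNEL_STR_COLS = ("name", "region")
_CHANNEL_BOOL_COLS = ("in_car", "bad", "in_hand_region")


def save_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=float(rec.fs))
        g = f.create_group("channels")
        for col in _CHANNEL_STR_COLS:
            g.create_dataset(col, data=np.array(rec.channels[col], dtype="S"))
        for col in _CHANNEL_BOOL_COLS:
            g.create_dataset(col, data=rec.channels[col].to_numpy(dtype=bool))


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        signal = f["signal"][()]
        fs = float(f["fs"][()])
        cols = {}
        for col in _CHANNEL_STR_COLS:
            cols[col] = [s.decode() for s in f["channels"][col][()]]
        for col in _CHANNEL_BOOL_COLS:
            cols[col] = f["channels"][col][()].astype(bool)
    return Recording(signal, fs, pd.DataFrame(cols))


def save_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def load_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    ev["excluded"] = ev["excluded"].astype(bool)
    return ev


def save_ground_truth(prefix, gt: GroundTruth) -> None:
    """Writes ``<prefix>_trials.csv`` (per-trial movement times) and
    ``<prefix>_channels.csv`` (per-channel true onsets and regions)."""
    prefix = Path(prefix)
    pd.DataFrame(
        {"trial_id": np.arange(gt.true_movement_time_s.size),
         "true_movement_time_s": gt.true_movement_time_s}
    ).to_csv(f"{prefix}_trials.csv", index=False)
    pd.DataFrame(
        {"channel_id": np.arange(gt.true_onset_s.size),
         "true_onset_s": gt.true_onset_s,
         "region": gt.region_of_channel}
    ).to_csv(f"{prefix}_channels.csv", index=False)


def load_ground_truth(prefix) -> GroundTruth:
    trials = pd.read_csv(f"{prefix}_trials.csv")
    chans = pd.read_csv(f"{prefix}_channels.csv")
    return GroundTruth(
        trials["true_movement_time_s"].to_numpy(),
        chans["true_onset_s"].to_numpy(),
        chans["region"].tolist(),
    )


def load_synth_config(path) -> SynthConfig:
    """SynthConfig from a YAML (or JSON, a YAML subset) keyed text file."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    fields = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("fingers", "region_of_channel", "true_onset_s", "bad_channel_ids",
                "intertrial_range_s"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SynthConfig(**raw)


def save_band_power(path, bp: BandPower) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=bp.data)
        f.create_dataset("time_s", data=bp.time_s)
        f.create_dataset("fs", data=float(bp.fs))
        f.create_dataset("fingers", data=np.array(bp.fingers, dtype="S"))
        f.create_dataset("trial_ids", data=bp.trial_ids)
        f.attrs["band_name"] = bp.band.name
        f.attrs["band_low"] = bp.band.low
        f.attrs["band_high"] = bp.band.high
        f.attrs["band_direction"] = bp.band.direction
        g = f.create_group("channels")
        for col in _CHANNEL_STR_COLS:
            g.create_dataset(col, data=np.array(bp.channels[col], dtype="S"))
        for col in _CHANNEL_BOOL_COLS:
            g.create_dataset(col, data=bp.channels[col].to_numpy(dtype=bool))


def load_band_power(path) -> BandPower:
    with h5py.File(path, "r") as f:
        band = BandSpec(
            f.attrs["band_name"], float(f.attrs["band_low"]),
            float(f.attrs["band_high"]), f.attrs["band_direction"],
        )
        cols = {}
        for col in _CHANNEL_STR_COLS:
            cols[col] = [s.decode() for s in f["channels"][col][()]]
        for col in _CHANNEL_BOOL_COLS:
            cols[col] = f["channels"][col][()].astype(bool)
        return BandPower(
            f["power"][()], f["time_s"][()], float(f["fs"][()]),
            np.array([s.decode() for s in f["fingers"][()]]),
            pd.DataFrame(cols), f["trial_ids"][()], band=band,
        )


def save_glove(path, glove: GloveTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=glove.traces)
        f.create_dataset("fingers", data=np.array(glove.fingers, dtype="S"))
        f.create_dataset("fs", data=float(glove.fs))


def load_glove(path) -> GloveTrace:
    with h5py.File(path, "r") as f:
        return GloveTrace(
            f["traces"][()], [s.decode() for s in f["fingers"][()]], float(f["fs"][()])
        )


def save_trialset(path, ts: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("time_s", data=ts.time_s)
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("fingers", data=np.array(ts.fingers, dtype="S"))
        f.create_dataset("trial_ids", data=ts.trial_ids)
        g = f.create_group("channels")
        for col in _CHANNEL_STR_COLS:
            g.create_dataset(col, data=np.array(ts.channels[col], dtype="S"))
        for col in _CHANNEL_BOOL_COLS:
            g.create_dataset(col, data=ts.channels[col].to_numpy(dtype=bool))


def load_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        cols = {}
        for col in _CHANNEL_STR_COLS:
            cols[col] = [s.decode() for s in f["channels"][col][()]]
        for col in _CHANNEL_BOOL_COLS:
            cols[col] = f["channels"][col][()].astype(bool)
        return TrialSet(
            f["data"][()], f["time_s"][()], float(f["fs"][()]),
            np.array([s.decode() for s in f["fingers"][()]]),
            pd.DataFrame(cols), f["trial_ids"][()],
        )


def save_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
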