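"""File formats: HDF5 and CSV spike data, stimulus logs, raw traces, configs.

HDF5 layout::

    /spikes/<electrode_id>   float64 spike times (s)
    /layout                  electrode table (id, col, row, region, excluded)
    /stimulus/times          float64 stimulus times (s)
    attrs: duration_s, sampling_hz, stim_electrode, ...

CSV spike dialect is two columns ``electrode_id,time_s`` with a header.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import RawRecording, SpikeData, StimulusLog
from .layout import Electrode, ElectrodeLayout, default_layout, ROW_REGIONS

__all__ = [
    "write_spikes_h5", "read_spikes_h5",
    "write_spikes_csv", "read_spikes_csv",
    "write_stimulus_csv", "read_stimulus_csv",
    "write_raw_h5", "read_raw_h5",
    "write_bursts_csv", "write_trials_csv",
    "load_config", "save_config",
]


def _write_layout(f: h5py.File, layout: ElectrodeLayout, excluded) -> None:
    grp = f.create_group("layout")
    ids = np.array([e.id for e in layout.electrodes], dtype="S8")
    grp.create_dataset("id", data=ids)
    grp.create_dataset("col", data=np.array([e.col for e in layout.electrodes]))
    grp.create_dataset("row", data=np.array([e.row for e in layout.electrodes]))
    grp.create_dataset("excluded", data=np.array(
        [e.id in excluded for e in layout.electrodes]))


def _read_layout(f: h5py.File) -> tuple[ElectrodeLayout, frozenset]:
    if "layout" not in f:
        return default_layout(), frozenset()
    grp = f["layout"]
    ids = [i.decode() for i in grp["id"][:]]
    cols = grp["col"][:]
    rows = grp["row"][:]
    from .layout import PITCH_UM
    elecs = tuple(
        Electrode(i, int(c), int(r), ROW_REGIONS[int(r)],
                  (int(c) - 1) * PITCH_UM, (int(r) - 1) * PITCH_UM)
        for i, c, r in zip(ids, cols, rows))
    excl = frozenset(i for i, x in zip(ids, grp["excluded"][:]) if x)
    return ElectrodeLayout(elecs), excl


def write_spikes_h5(spikes: SpikeData, path, stim: StimulusLog | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = spikes.duration
        grp = f.create_group("spikes")
        for eid, t in spikes.trains.items():
            grp.create_dataset(eid, data=t, dtype="f8")
        _write_layout(f, spikes.layout, spikes.excluded)
        if stim is not None:
            sg = f.create_group("stimulus")
            sg.create_dataset("times", data=stim.times, dtype="f8")
            sg.attrs["electrode"] = stim.electrode
            sg.attrs["amplitude_mv"] = stim.amplitude_mv
            sg.attrs["phase_us"] = stim.phase_us
            sg.attrs["max_stimuli"] = stim.max_stimuli


def read_spikes_h5(path) -> tuple[SpikeData, StimulusLog | None]:
    with h5py.File(path, "r") as f:
        layout, excl = _read_layout(f)
        trains = {eid: ds[:] for eid, ds in f["spikes"].items()}
        spikes = SpikeData(trains=trains, duration=float(f.attrs["duration_s"]),
                           layout=layout, excluded=excl)
        stim = None
        if "stimulus" in f:
            sg = f["stimulus"]
            stim = StimulusLog(times=sg["times"][:],
                               electrode=str(sg.attrs["electrode"]),
                               amplitude_mv=float(sg.attrs["amplitude_mv"]),
                               phase_us=float(sg.attrs["phase_us"]),
                               max_stimuli=int(sg.attrs["max_stimuli"]))
    return spikes, stim


def write_spikes_csv(spikes: SpikeData, path) -> None:
    rows = [(eid, t) for eid in sorted(spikes.trains) for t in spikes.trains[eid]]
    pd.DataFrame(rows, columns=["electrode_id", "time_s"]).to_csv(path, index=False)


def read_spikes_csv(path, duration: float | None = None,
                    layout: ElectrodeLayout | None = None) -> SpikeData:
    df = pd.read_csv(path, dtype={"electrode_id": str})
    trains = {}
    for eid, grp in df.groupby("electrode_id"):
        t = grp["time_s"].to_numpy(dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"electrode {eid}: unsorted spike times in {path}")
        trains[eid] = t
    if duration is None:
        duration = float(df["time_s"].max()) + 1.0 if len(df) else 1.0
    return SpikeData(trains=trains, duration=duration, layout=layout or default_layout())


def write_stimulus_csv(stim: StimulusLog, path) -> None:
    pd.DataFrame({"time_s": stim.times}).to_csv(path, index=False)
    meta = Path(path).with_suffix(".json")
    meta.write_text(json.dumps({
        "electrode": stim.electrode, "amplitude_mv": stim.amplitude_mv,
        "phase_us": stim.phase_us, "max_stimuli": stim.max_stimuli}))


def read_stimulus_csv(path) -> StimulusLog:
    times = pd.read_csv(path)["time_s"].to_numpy(dtype=float)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return StimulusLog(times=times, electrode=meta.get("electrode", ""),
                       amplitude_mv=meta.get("amplitude_mv", 800.0),
                       phase_us=meta.get("phase_us", 200.0),
                       max_stimuli=meta.get("max_stimuli", max(60, len(times))))


def write_raw_h5(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_hz"] = rec.sampling_hz
        f.attrs["start_s"] = rec.start
        grp = f.create_group("raw")
        for eid, x in rec.traces.items():
            grp.create_dataset(eid, data=x, dtype="f8")
        _write_layout(f, rec.layout, rec.excluded)


def read_raw_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        layout, excl = _read_layout(f)
        traces = {eid: ds[:] for eid, ds in f["raw"].items()}
        return RawRecording(traces=traces, sampling_hz=float(f.attrs["sampling_hz"]),
                            start=float(f.attrs["start_s"]), layout=layout,
                            excluded=excl)


def write_bursts_csv(bursts_by_region: dict, path) -> None:
    rows = [
        {"region": region, "start_s": b.start, "end_s": b.end,
         "n_electrodes": b.n_electrodes, "n_spikes": b.n_spikes}
        for region, events in bursts_by_region.items() for b in events
    ]
    pd.DataFrame(rows, columns=["region", "start_s", "end_s",
                                "n_electrodes", "n_spikes"]).to_csv(path, index=False)


def write_trials_csv(trials, path) -> None:
    rows = []
    for t in trials:
        rows.append({
            "stimulus_time_s": t.stimulus_time,
            "a_burst": t.a_burst, "b_burst": t.b_burst,
            "delay_ms": t.delay_ms,
            "latency10_ms": t.latency_diff_ms(0.1),
            "latency20_ms": t.latency_diff_ms(0.2),
            "latency50_ms": t.latency_diff_ms(0.5),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
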