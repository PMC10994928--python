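"""File formats: spike-time CSV/HDF5, metrics JSON, TIFF image stacks.

Spike tables are tidy CSV with columns ``well_id, electrode_id,
spike_time_s``; recording-level metadata (duration, condition, timepoint,
stimulation epochs) travels in a JSON sidecar or HDF5 attributes.  Images
are 16-bit multi-page TIFF (nuclei / apoptosis / death page order) with a
JSON label sidecar when ground truth is available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bursts import WellMetrics
from .core import SpikeTrain, WellRecording
from .simulate import CellImageSet, GroundTruth, NetworkBurstTruth

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_spike_hdf5",
    "read_spike_hdf5",
    "write_metrics_json",
    "read_metrics_json",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_image_set",
    "read_image_set",
]


def write_spike_csv(recordings: Sequence[WellRecording], path) -> None:
    rows = []
    for rec in recordings:
        for eid, train in rec.trains.items():
            for t in train.times:
                rows.append((rec.well_id, eid, float(t)))
    df = pd.DataFrame(rows, columns=["well_id", "electrode_id", "spike_time_s"])
    df.to_csv(path, index=False)
    meta = {
        rec.well_id: {
            "duration": rec.duration,
            "condition": rec.condition,
            "timepoint_h": rec.timepoint_h,
            "stimulation_epochs": [list(e) for e in rec.stimulation_epochs],
            "electrode_ids": rec.electrode_ids,
        }
        for rec in recordings
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_spike_csv(path, duration: Optional[float] = None) -> List[WellRecording]:
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    recs = []
    for well_id, sub in df.groupby("well_id", sort=True):
        info = meta.get(str(well_id), {})
        dur = info.get("duration", duration)
        if dur is None:
            raise ValueError("recording duration unknown: pass duration= or keep the sidecar")
        eids = info.get("electrode_ids") or sorted(sub["electrode_id"].unique())
        trains = {}
        for eid in eids:
            t = np.sort(sub.loc[sub["electrode_id"] == eid, "spike_time_s"].to_numpy())
            trains[eid] = SpikeTrain(np.unique(t), dur, eid)
        recs.append(
            WellRecording(
                trains=trains,
                duration=dur,
                well_id=str(well_id),
                condition=info.get("condition", "unknown"),
                timepoint_h=info.get("timepoint_h", 0.0),
                stimulation_epochs=[tuple(e) for e in info.get("stimulation_epochs", [])],
            )
        )
    return recs


def write_spike_hdf5(recordings: Sequence[WellRecording], path) -> None:
    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(f"wells/{rec.well_id}")
            g.attrs["duration"] = rec.duration
            g.attrs["condition"] = rec.condition
            g.attrs["timepoint_h"] = rec.timepoint_h
            g.attrs["stimulation_epochs"] = np.array(rec.stimulation_epochs, dtype=float).reshape(-1, 2)
            for eid, train in rec.trains.items():
                g.create_dataset(f"electrodes/{eid}", data=train.times)


def read_spike_hdf5(path) -> List[WellRecording]:
    recs = []
    with h5py.File(path, "r") as f:
        for well_id in sorted(f["wells"]):
            g = f[f"wells/{well_id}"]
            dur = float(g.attrs["duration"])
            trains = {
                eid: SpikeTrain(np.asarray(g[f"electrodes/{eid}"]), dur, eid)
                for eid in sorted(g["electrodes"])
            }
            recs.append(
                WellRecording(
                    trains=trains,
                    duration=dur,
                    well_id=well_id,
                    condition=str(g.attrs.get("condition", "unknown")),
                    timepoint_h=float(g.attrs.get("timepoint_h", 0.0)),
                    stimulation_epochs=[tuple(e) for e in np.asarray(g.attrs.get("stimulation_epochs", np.empty((0, 2))))],
                )
            )
    return recs


def write_metrics_json(metrics: Sequence[WellMetrics], path) -> None:
    payload = [dataclasses.asdict(m) for m in metrics]
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def read_metrics_json(path) -> List[WellMetrics]:
    payload = json.loads(Path(path).read_text())
    return [WellMetrics(**item) for item in payload]


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "spike_times": {k: np.asarray(v).tolist() for k, v in truth.spike_times.items()},
        "network_bursts": [
            {"start": e.start, "end": e.end, "electrodes": list(e.electrodes)}
            for e in truth.network_bursts
        ],
        "multipliers": truth.multipliers,
        "cell_labels": truth.cell_labels,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        spike_times={k: np.asarray(v) for k, v in payload["spike_times"].items()},
        network_bursts=[
            NetworkBurstTruth(e["start"], e["end"], tuple(e["electrodes"]))
            for e in payload["network_bursts"]
        ],
        multipliers=payload.get("multipliers", {}),
        cell_labels=[tuple(lab) for lab in payload["cell_labels"]] if payload.get("cell_labels") else None,
    )


def write_image_set(images: CellImageSet, path, labels: Optional[list] = None) -> None:
    stack = np.stack(
        [images.nuclei_channel, images.apoptosis_channel, images.death_channel]
    ).astype(np.uint16)
    tifffile.imwrite(
        path, stack, photometric="minisblack", planarconfig="separate", metadata={"axes": "CYX"}
    )
    if labels is not None:
        Path(str(path) + ".labels.json").write_text(json.dumps(labels))


def read_image_set(path, assay_variant: str = "caspase_pi") -> CellImageSet:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError("expected a 3-page (nuclei/apoptosis/death) TIFF")
    return CellImageSet(
        nuclei_channel=stack[0],
        apoptosis_channel=stack[1],
        death_channel=stack[2],
        assay_variant=assay_variant,
    )
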