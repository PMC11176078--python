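"""File formats: pose CSV, bout CSV, trace HDF5, provenance JSON."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "write_pose_csv", "read_pose_csv",
    "write_bouts_csv", "read_bouts_csv",
    "write_traces_h5", "read_traces_h5",
    "write_provenance",
]


def write_pose_csv(path, pose: pd.DataFrame) -> None:
    pose.to_csv(path, index=False)


def read_pose_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bouts_csv(path, bouts: pd.DataFrame) -> None:
    bouts.to_csv(path, index=False)


def read_bouts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_traces_h5(path, traces_by_fish: dict) -> None:
    """Layout: /fish/<id>/raw (neurons x time), /fish/<id>/neuron_ids."""
    import h5py

    with h5py.File(path, "w") as fh:
        for fish_id, (raw, neuron_ids) in traces_by_fish.items():
            grp = fh.create_group(f"fish/{fish_id}")
            grp.create_dataset("raw", data=np.asarray(raw))
            grp.create_dataset("neuron_ids",
                               data=np.asarray(neuron_ids, dtype="S"))


def read_traces_h5(path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for fish_id in fh["fish"]:
            grp = fh[f"fish/{fish_id}"]
            ids = [s.decode() for s in grp["neuron_ids"][()]]
            out[fish_id] = (grp["raw"][()], ids)
    return out


def write_provenance(path, **fields) -> None:
    """Record how an artifact was generated (seed, config, versions)."""
    payload = {
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        **fields,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
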