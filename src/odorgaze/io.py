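"""File formats: HDF5 trial containers, tidy CSV mirrors, JSON sidecars.

One HDF5 file holds one synthetic (or recorded) trial: datasets ``/time``,
``/stimulus``, ``/response`` plus free-form scalar attributes under
``/meta``.  Every written trial can be mirrored as a tidy long CSV
(columns ``time_s, channel, value``) and is accompanied by a JSON sidecar
recording the seed and all generator parameters, so a dataset is fully
reconstructable from its sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "write_trial_h5",
    "read_trial_h5",
    "write_tidy_csv",
    "write_sidecar",
    "read_sidecar",
    "jsonable",
]


def jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_trial_h5(
    path, time: np.ndarray, stimulus: np.ndarray | None, response: np.ndarray,
    meta: dict | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=np.asarray(time, dtype=float))
        if stimulus is not None:
            fh.create_dataset("stimulus", data=np.asarray(stimulus, dtype=float))
        fh.create_dataset("response", data=np.asarray(response, dtype=float))
        grp = fh.create_group("meta")
        for key, value in (meta or {}).items():
            grp.attrs[key] = value
    return path


def read_trial_h5(path) -> dict:
    with h5py.File(path, "r") as fh:
        out = {
            "time": fh["time"][:],
            "stimulus": fh["stimulus"][:] if "stimulus" in fh else None,
            "response": fh["response"][:],
            "meta": {k: v for k, v in fh["meta"].attrs.items()} if "meta" in fh else {},
        }
    return out


def write_tidy_csv(path, time: np.ndarray, channels: dict) -> Path:
    """Long-format mirror: columns time_s, channel, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame({"time_s": time, "channel": name, "value": values})
        for name, values in channels.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    return path


def write_sidecar(path, seed: int, params: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"seed": int(seed), "params": jsonable(params)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
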