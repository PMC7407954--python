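"""State and model serialization for reproducibility audits.

Layer parameters are dumped to flat CSV (one row per matrix entry, columns
``layer, matrix, row, col, value``); a model checkpoint is a directory with
both networks' CSVs plus a JSON manifest recording seed, lesion flag and the
full configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CouplingConfig, LearningConfig
from .core import QuantumLayerParams
from .cortex import CorticalState
from .hippocampus import HippocampalState
from .model import CHCQModel

__all__ = ["state_to_frame", "frame_to_params", "save_state", "load_state",
           "save_checkpoint"]

_MATRICES = ("W", "eps", "theta")


def state_to_frame(state) -> pd.DataFrame:
    """Flatten a two-layer state into a tidy frame of parameter entries."""
    rows = []
    for lname in ("layer1", "layer2"):
        params: QuantumLayerParams = getattr(state, lname)
        for mname in _MATRICES:
            m = getattr(params, mname)
            for (i, j), v in np.ndenumerate(m):
                rows.append((lname, mname, i, j, v))
    return pd.DataFrame(rows, columns=["layer", "matrix", "row", "col", "value"])


def frame_to_params(df: pd.DataFrame, layer: str) -> QuantumLayerParams:
    sub = df[df["layer"] == layer]
    mats = {}
    for mname in _MATRICES:
        ms = sub[sub["matrix"] == mname]
        n_in = int(ms["row"].max()) + 1
        n_units = int(ms["col"].max()) + 1
        m = np.empty((n_in, n_units))
        m[ms["row"].to_numpy(), ms["col"].to_numpy()] = ms["value"].to_numpy()
        mats[mname] = m
    return QuantumLayerParams(mats["W"], mats["eps"], mats["theta"])


def save_state(state, path) -> None:
    state_to_frame(state).to_csv(path, index=False)


def load_state(path, kind: str):
    """Load a serialized state; ``kind`` is "hippocampal" or "cortical"."""
    df = pd.read_csv(path)
    l1 = frame_to_params(df, "layer1")
    l2 = frame_to_params(df, "layer2")
    cls = HippocampalState if kind == "hippocampal" else CorticalState
    return cls(l1, l2)


def save_checkpoint(model: CHCQModel, directory) -> Path:
    """Write a model checkpoint directory (two CSVs + manifest.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_state(model.hippocampus, directory / "hippocampus.csv")
    save_state(model.cortex, directory / "cortex.csv")
    manifest = {
        "seed": model.seed,
        "lesioned": model.lesioned,
        "r": model.r,
        "q": model.q,
        "trial_count": model.trial_count,
        "learning": asdict(model.learning),
        "coupling": asdict(model.coupling),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory
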