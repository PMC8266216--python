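"""CSV/JSON serialization for populations, network states and metrics."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .entorhinal import EntorhinalPopulation, GridParams, RealisticFieldParams
from .environment import Environment
from .network import NetworkState

__all__ = [
    "save_population",
    "load_population",
    "save_state",
    "load_state",
]


def _params_to_json(meta) -> dict | None:
    if meta is None:
        return None
    if isinstance(meta, RealisticFieldParams):
        return {
            "type": "realistic",
            "grid": meta.grid.to_dict(),
            "sigma_cm": meta.sigma_cm,
            "module": meta.module,
            "vertices_cm": np.asarray(meta.vertices_cm).tolist(),
            "amplitudes": np.asarray(meta.amplitudes).tolist(),
        }
    if isinstance(meta, GridParams):
        return {"type": "math", **meta.to_dict()}
    raise TypeError(f"unsupported per-cell metadata {type(meta)!r}")


def _params_from_json(d: dict | None):
    if d is None:
        return None
    if d["type"] == "math":
        return GridParams(d["spacing_cm"], d["orientation_rad"], tuple(d["phase_cm"]))
    g = d["grid"]
    return RealisticFieldParams(
        grid=GridParams(g["spacing_cm"], g["orientation_rad"], tuple(g["phase_cm"])),
        vertices_cm=np.asarray(d["vertices_cm"], dtype=float),
        amplitudes=np.asarray(d["amplitudes"], dtype=float),
        sigma_cm=d["sigma_cm"],
        module=d.get("module", 0),
    )


def save_population(pop: EntorhinalPopulation, prefix: str | Path) -> None:
    """Write fields to ``<prefix>.csv`` and metadata to ``<prefix>.json``."""
    prefix = Path(prefix)
    pd.DataFrame(pop.E).to_csv(prefix.with_suffix(".csv"), index=False)
    meta = {
        "kind": pop.kind,
        "env": pop.env.to_dict(),
        "params": [_params_to_json(p) for p in pop.params],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_population(prefix: str | Path) -> EntorhinalPopulation:
    prefix = Path(prefix)
    E = pd.read_csv(prefix.with_suffix(".csv")).to_numpy(dtype=float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EntorhinalPopulation(
        E=E,
        kind=meta["kind"],
        env=Environment.from_dict(meta["env"]),
        params=[_params_from_json(p) for p in meta["params"]],
    )


def save_state(state: NetworkState, prefix: str | Path) -> None:
    """Write the dictionary A to CSV; W is recomputed on load."""
    prefix = Path(prefix)
    pd.DataFrame(state.A).to_csv(prefix.with_suffix(".csv"), index=False)
    prefix.with_suffix(".json").write_text(
        json.dumps({"n_dead_respawns": state.n_dead_respawns})
    )


def load_state(prefix: str | Path) -> NetworkState:
    prefix = Path(prefix)
    A = pd.read_csv(prefix.with_suffix(".csv")).to_numpy(dtype=float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    state = NetworkState(A=A, W=np.empty((A.shape[1], A.shape[1])))
    state.recompute_w()
    state.n_dead_respawns = meta.get("n_dead_respawns", 0)
    return state
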