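"""Named experiment presets: input generation, training and analysis end-to-end.

Each preset bundles the input-population recipe, the network
hyperparameters and the recovery/analysis settings for one published
experiment configuration (diverse mathematical grids, module-sampled
realistic grids, diversity ablations, large-spacing inputs, weakly spatial
inputs, response noise, a stretched arena, trajectory-based training).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import analyze_place_map
from .entorhinal import (
    EntorhinalPopulation,
    ModuleSpec,
    make_math_grid_population,
    make_weakly_spatial_population,
    sample_realistic_grid_population,
    stretch_population,
)
from .environment import Environment, make_environment
from .network import ModelConfig, train
from .trajectory import simulate_trajectory

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "get_preset",
    "list_presets",
    "run_experiment",
    "diversity_ablation",
    "run_nh_sweep",
]


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    input_kind: str  # grid_math | grid_realistic | weak_spatial
    input_params: dict = field(default_factory=dict)
    model: ModelConfig = field(default_factory=ModelConfig)
    recovery_samples: int = 100_000
    stretch_factor: float = 1.0
    location_source: str = "uniform"  # uniform | trajectory
    train_trajectory_s: float = 3600.0
    recovery_trajectory_s: float = 1200.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _math(name: str, counts: tuple[int, int, int, int], **model_kw) -> ExperimentConfig:
    n_l, n_t, n_x, n_y = counts
    return ExperimentConfig(
        name=name,
        input_kind="grid_math",
        input_params={
            "n_spacings": n_l,
            "n_orientations": n_t,
            "n_phases_x": n_x,
            "n_phases_y": n_y,
        },
        model=ModelConfig(**model_kw),
    )


def _realistic(name: str, module_kw: Optional[dict] = None, **kw) -> ExperimentConfig:
    model_kw = {k: v for k, v in kw.items() if k in ModelConfig.__dataclass_fields__}
    other = {k: v for k, v in kw.items() if k not in ModelConfig.__dataclass_fields__}
    return ExperimentConfig(
        name=name,
        input_kind="grid_realistic",
        input_params={"n_cells": 600, "module_spec": module_kw or {}, **other.pop("input", {})},
        model=ModelConfig(**model_kw),
        **other,
    )


def _weak(name: str, **kw) -> ExperimentConfig:
    model_kw = {k: v for k, v in kw.items() if k in ModelConfig.__dataclass_fields__}
    other = {k: v for k, v in kw.items() if k not in ModelConfig.__dataclass_fields__}
    return ExperimentConfig(
        name=name,
        input_kind="weak_spatial",
        input_params={"n_cells": 600, "smooth_sd_cm": 6.0},
        model=ModelConfig(eta=0.01, n_epochs=30000, **model_kw),
        **other,
    )


def _build_presets() -> dict[str, ExperimentConfig]:
    presets = {
        # diverse mathematical grids: 600 cells, 100 hippocampal cells
        "fig3": _math("fig3", (4, 6, 5, 5)),
        # diversity ablations of the mathematical model
        "fig5_spacing": _math("fig5_spacing", (1, 6, 5, 5)),
        "fig5_orientation": _math("fig5_orientation", (4, 1, 5, 5)),
        "fig5_phase": _math("fig5_phase", (4, 6, 1, 1)),
        # module-sampled realistic grids
        "fig8": _realistic("fig8"),
        # realistic-model diversity ablations
        "fig8_spacing": _realistic("fig8_spacing", module_kw={"spacing_sd_cm": 0.0}),
        "fig8_orientation": _realistic(
            "fig8_orientation",
            module_kw={"spacing_sd_cm": 4.0, "orientation_sd_deg": 0.0},
        ),
        "fig8_phase": _realistic(
            "fig8_phase", input={"fixed_phase_cm": (0.0, 0.0)}
        ),
        # two smallest modules only
        "fig9": _realistic(
            "fig9", module_kw={"proportions": (0.5, 0.5, 0.0, 0.0)}
        ),
        # largest-spacing module only, 20 hippocampal cells -> large fields
        "fig10": _realistic(
            "fig10",
            module_kw={"proportions": (0.0, 0.0, 0.0, 1.0)},
            n_hippocampal=20,
        ),
        # weakly spatial inputs (smaller learning rate, more epochs)
        "fig11": _weak("fig11"),
        # weakly spatial inputs with response noise
        "fig12": _weak("fig12", noise_amp=0.3),
        # stretched arena: train as fig8, recover with fields stretched x2
        "fig13": _realistic("fig13", stretch_factor=2.0),
        # trajectory-based training and recovery
        "fig14": _realistic(
            "fig14", location_source="trajectory", n_epochs=72000
        ),
    }
    return presets


PRESETS = _build_presets()


def list_presets() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str, **overrides) -> ExperimentConfig:
    """Resolve a preset by name, optionally overriding model fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}")
    config = PRESETS[name]
    model_kw = {k: v for k, v in overrides.items() if k in ModelConfig.__dataclass_fields__}
    other = {k: v for k, v in overrides.items() if k not in ModelConfig.__dataclass_fields__}
    if model_kw:
        config = replace(config, model=replace(config.model, **model_kw))
    if other:
        config = replace(config, **other)
    return config


def build_input_population(
    config: ExperimentConfig, env: Environment, rng: np.random.Generator
) -> EntorhinalPopulation:
    p = dict(config.input_params)
    if config.input_kind == "grid_math":
        return make_math_grid_population(env, **p)
    if config.input_kind == "grid_realistic":
        spec = ModuleSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in p.pop("module_spec", {}).items()
        })
        return sample_realistic_grid_population(env, spec, rng=rng, **p)
    if config.input_kind == "weak_spatial":
        return make_weakly_spatial_population(
            env, p["n_cells"], rng, smooth_sd_cm=p.get("smooth_sd_cm", 6.0)
        )
    raise ValueError(f"unknown input kind {config.input_kind!r}")


def run_experiment(
    config: ExperimentConfig,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run one preset end-to-end and return the summary metrics.

    Pipeline: generate inputs -> train -> (optionally stretch the fields)
    -> recover firing fields by reverse correlation -> fit -> classify ->
    tiling metrics.  When ``out_dir`` is given, the resolved config, the
    metrics, the per-cell fit table, the recovered fields and the training
    log are written there.
    """
    rng = np.random.default_rng(seed)
    env = make_environment()
    pop = build_input_population(config, env, rng)

    location_source = None
    if config.location_source == "trajectory":
        traj = simulate_trajectory(env, duration_s=config.train_trajectory_s, rng=rng)
        location_source = traj.to_location_indices(env)
    elif config.location_source != "uniform":
        raise ValueError(f"unknown location source {config.location_source!r}")

    state = train(pop, config.model, rng, location_source=location_source)

    recovery_pop = pop
    if config.stretch_factor > 1:
        recovery_pop = stretch_population(pop, config.stretch_factor)
    recovery_locations = None
    if config.location_source == "trajectory":
        rec_traj = simulate_trajectory(
            recovery_pop.env, duration_s=config.recovery_trajectory_s, rng=rng
        )
        recovery_locations = rec_traj.to_location_indices(recovery_pop.env)

    metrics, table, fields = analyze_place_map(
        state,
        recovery_pop,
        config.model,
        n_samples=config.recovery_samples,
        rng=rng,
        recovery_locations=recovery_locations,
    )
    results = {
        "preset": config.name,
        "seed": seed,
        **metrics.to_dict(),
        "n_dead_respawns": state.n_dead_respawns,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps({**config.to_dict(), "seed": seed}, indent=2)
        )
        (out / "metrics.json").write_text(json.dumps(results, indent=2))
        table.to_csv(out / "cells.csv", index=False)
        field_matrix = np.column_stack([f.values for f in fields])
        pd.DataFrame(field_matrix).to_csv(out / "fields.csv", index=False)
        if state.training_log is not None:
            state.training_log.to_csv(out / "training_log.csv", index=False)
    results["cells"] = table
    results["metrics"] = metrics
    return results


_MATH_ABLATIONS = {
    "spacing": "fig5_spacing",
    "orientation": "fig5_orientation",
    "phase": "fig5_phase",
}
_REALISTIC_ABLATIONS = {
    "spacing": "fig8_spacing",
    "orientation": "fig8_orientation",
    "phase": "fig8_phase",
}


def diversity_ablation(
    config: ExperimentConfig, ablated_parameter: Optional[str]
) -> ExperimentConfig:
    """Collapse one grid-parameter dimension of a preset.

    For the mathematical model the corresponding count drops to 1; for the
    realistic model the module SD drops to 0 (or the phase is pinned at the
    origin).  ``None`` returns the config unchanged.
    """
    if ablated_parameter is None:
        return config
    table = (
        _MATH_ABLATIONS if config.input_kind == "grid_math" else _REALISTIC_ABLATIONS
    )
    if ablated_parameter not in table:
        raise ValueError(
            f"unknown ablation {ablated_parameter!r}; expected one of {sorted(table)}"
        )
    ablated = get_preset(table[ablated_parameter])
    return replace(
        ablated, name=f"{config.name}_{ablated_parameter}_ablated", model=config.model
    )


def run_nh_sweep(
    n_values: tuple[int, ...] = (10, 20, 30, 40, 50, 60),
    base: str = "fig3",
    seed: int = 0,
    **overrides,
) -> pd.DataFrame:
    """Re-run a preset at several hippocampal population sizes."""
    rows = []
    for n_h in n_values:
        config = get_preset(base, n_hippocampal=n_h, **overrides)
        res = run_experiment(config, seed=seed)
        rows.append(
            {
                "n_hippocampal": n_h,
                "n_place_cells": res["n_place_cells"],
                "mean_radius_cm": res["mean_radius_cm"],
                "sd_radius_cm": res["sd_radius_cm"],
                "mean_nearest_distance_cm": res["mean_nearest_distance_cm"],
                "sd_nearest_distance_cm": res["sd_nearest_distance_cm"],
            }
        )
    return pd.DataFrame(rows)
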