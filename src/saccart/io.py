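"""Configuration handling and persistent model/trace formats.

Model snapshots are self-describing HDF5 files: adaptive weights under
``/weights/<name>``, habituative gate levels under ``/gates/<name>``, and a
``/meta`` group holding the fully materialized run configuration (every
default filled in) plus the package version.  Event streams (search traces,
choice events) are written as JSON lines; time series and tidy tables as
CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import h5py
import numpy as np
import yaml

from . import __version__
from .art import ARTModel, SearchTrace
from .maps import ChoiceParams, SaccartModel, SpaceConfig

__all__ = [
    "RunConfig",
    "load_config",
    "save_art_model",
    "load_art_model",
    "save_saccart_model",
    "load_saccart_model",
    "traces_to_jsonl",
]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "runs",
    "verbose": False,
    # art
    "rho_base": 0.5,
    "n_categories": 64,
    "eta": 1.0,
    "mode": "binary",
    "supervised": False,
    "epsilon": 0.001,
    "ach_coupling": False,
    # scenario
    "scenario": {"kind": "binary_patterns", "params": {"n": 20, "d": 25, "overlap": 0.4}},
    # saccart geometry / training
    "n_cells": 41,
    "extent": 40.0,
    "sigma_g": 3.0,
    "plant_gain": 0.8,
    "n_trials": 200,
    "pairing": "colocated",
    "positions": [-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0],
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with every default materialized."""

    values: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def override(self, key: str, value: Any) -> None:
        if key not in _DEFAULTS:
            raise ValueError(f"unknown configuration key: {key}")
        current = _DEFAULTS[key]
        if isinstance(current, bool):
            value = str(value).lower() in ("1", "true", "yes")
        elif isinstance(current, (int, float)) and not isinstance(current, bool):
            value = type(current)(float(value))
        self.values[key] = value


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Read YAML or JSON configuration; missing path means all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    return RunConfig(values=data)


def _write_meta(f: h5py.File, config: Optional[RunConfig]) -> None:
    meta = f.require_group("meta")
    meta.attrs["package_version"] = __version__
    if config is not None:
        meta.attrs["config"] = json.dumps(config.values)


def save_art_model(model: ARTModel, path: str | Path,
                   config: Optional[RunConfig] = None) -> None:
    with h5py.File(path, "w") as f:
        w = f.create_group("weights")
        w.create_dataset("w_td", data=model.w_td)
        w.create_dataset("w_bu", data=model.w_bu)
        f.create_dataset("committed", data=sorted(model.committed))
        f.attrs["rho_base"] = model.orienting.rho_base
        f.attrs["mode"] = model.mode
        f.attrs["eta"] = model.eta
        f.attrs["alpha"] = model.alpha
        f.attrs["epsilon"] = model.epsilon
        _write_meta(f, config)


def load_art_model(path: str | Path) -> ARTModel:
    with h5py.File(path, "r") as f:
        w_td = f["weights/w_td"][...]
        model = ARTModel(
            n_features=w_td.shape[1],
            n_categories=w_td.shape[0],
            rho_base=float(f.attrs["rho_base"]),
            mode=str(f.attrs["mode"]),
            eta=float(f.attrs["eta"]),
            alpha=float(f.attrs["alpha"]),
            epsilon=float(f.attrs["epsilon"]),
        )
        model.w_td = w_td
        model.w_bu = f["weights/w_bu"][...]
        model.committed = set(int(j) for j in f["committed"][...])
    return model


def save_saccart_model(model: SaccartModel, path: str | Path,
                       config: Optional[RunConfig] = None,
                       gates: Optional[np.ndarray] = None) -> None:
    with h5py.File(path, "w") as f:
        w = f.create_group("weights")
        w.create_dataset("vam_w", data=model.vam_w)
        w.create_dataset("vam_trained", data=model.vam_trained)
        w.create_dataset("gain", data=model.gain)
        w.create_dataset("som_proto", data=model.som_proto)
        w.create_dataset("m2m", data=model.m2m)
        w.create_dataset("m2m_trained", data=model.m2m_trained)
        if gates is not None:
            f.create_group("gates").create_dataset("map", data=gates)
        f.attrs["d"] = model.space.d
        f.attrs["extent"] = model.space.extent
        f.attrs["n_cells"] = model.space.n_cells
        f.attrs["sigma_g"] = model.sigma_g
        f.attrs["sigma_som"] = model.sigma_som
        f.attrs["plant_gain"] = model.plant_gain
        _write_meta(f, config)


def load_saccart_model(path: str | Path) -> SaccartModel:
    with h5py.File(path, "r") as f:
        space = SpaceConfig(
            d=int(f.attrs["d"]),
            extent=float(f.attrs["extent"]),
            n_cells=int(f.attrs["n_cells"]),
        )
        model = SaccartModel(
            space=space,
            sigma_g=float(f.attrs["sigma_g"]),
            sigma_som=float(f.attrs["sigma_som"]),
            plant_gain=float(f.attrs["plant_gain"]),
        )
        w = f["weights"]
        model.vam_w = w["vam_w"][...]
        model.vam_trained = w["vam_trained"][...].astype(bool)
        model.gain = w["gain"][...]
        model.som_proto = w["som_proto"][...]
        model.m2m = w["m2m"][...]
        model.m2m_trained = w["m2m_trained"][...].astype(bool)
    return model


def traces_to_jsonl(traces: list[SearchTrace], path: str | Path) -> None:
    """Export per-presentation search traces as JSON lines."""
    with open(path, "w") as f:
        for tr in traces:
            rec = {
                "steps": [
                    {"category": s.category, "match_ratio": s.match_ratio,
                     "outcome": s.outcome}
                    for s in tr.steps
                ],
                "final_category": tr.final_category,
                "rho_final": tr.rho_final,
            }
            f.write(json.dumps(rec) + "\n")
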