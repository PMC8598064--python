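"""Configuration files, output writers and run manifests.

A configuration file is YAML (or an equivalent dict) naming a packaged
example and overriding parameter blocks::

    example: 3a
    seed: 1
    overrides:
      kinetics: {b3_hat: 500}
      mechanics: {alpha_hat: 1.0e6}
      numerics:  {n_steps: 100}
      grid:      {nx: 41, ny: 41, h: 0.01}
      init:      {seed_size: 1}

Unknown keys are rejected with their full field path.  A run writes
``metrics.csv`` (one row per step), plain-text snapshot arrays with a JSON
sidecar naming the component order, and a ``manifest.json`` that fully
determines reproduction of the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .grid import Grid
from .params import ChemicalParams, Mechanics
from .scenarios import ScenarioConfig, example_config, list_examples

__all__ = ["load_config", "dump_config", "write_outputs", "read_manifest"]

_VERSION = "0.1.0"

_BLOCKS = ("kinetics", "mechanics", "numerics", "chemical", "init", "grid")


def _apply_fields(obj, updates: dict, path: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in updates.items():
        if key not in names:
            raise ValueError(f"unknown config field {path}.{key}")
        setattr(obj, key, val)
    # re-validate
    obj.__post_init__()
    return obj


def load_config(source: Union[str, Path, dict]) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML file path or an equivalent dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    allowed = {"example", "seed", "overrides"}
    for key in doc:
        if key not in allowed:
            raise ValueError(f"unknown config field {key}")
    name = doc.get("example")
    if name not in list_examples():
        raise ValueError(f"example must be one of {', '.join(list_examples())}, "
                         f"got {name!r}")
    cfg = example_config(name)
    over = doc.get("overrides") or {}
    for key in over:
        if key not in _BLOCKS:
            raise ValueError(f"unknown config field overrides.{key}")

    if "grid" in over:
        g = dict(over["grid"])
        for key in g:
            if key not in ("nx", "ny", "h"):
                raise ValueError(f"unknown config field overrides.grid.{key}")
        cfg.grid = Grid(int(g.get("nx", cfg.grid.nx)), int(g.get("ny", cfg.grid.ny)),
                        float(g.get("h", cfg.grid.h)))
    if "kinetics" in over:
        _apply_fields(cfg.kin, over["kinetics"], "overrides.kinetics")
    if "mechanics" in over:
        m = dict(over["mechanics"])
        if "alpha_hat" in m:
            k = m.pop("k", list(cfg.mech.k))
            if len(k) != len(cfg.names):
                raise ValueError(
                    f"overrides.mechanics.k must list one k_i per component "
                    f"({len(cfg.names)}), got {len(k)}")
            cfg.mech = Mechanics.equal_drag(k, float(m.pop("alpha_hat")),
                                            m.pop("u0_opt", cfg.mech.u0_opt))
        if "k" in m:
            k = np.asarray(m.pop("k"), dtype=float)
            if len(k) != len(cfg.names):
                raise ValueError(
                    f"overrides.mechanics.k must list one k_i per component "
                    f"({len(cfg.names)}), got {len(k)}")
            cfg.mech.k = k
        if "drag" in m:
            cfg.mech.drag = np.asarray(m.pop("drag"), dtype=float)
        if "u0_opt" in m:
            cfg.mech.u0_opt = m.pop("u0_opt")
        if m:
            raise ValueError(
                f"unknown config field overrides.mechanics.{next(iter(m))}")
        cfg.mech.__post_init__()
    if "numerics" in over:
        _apply_fields(cfg.num, over["numerics"], "overrides.numerics")
    if "chemical" in over:
        if cfg.chem is None:
            cfg.chem = ChemicalParams()
        ch = dict(over["chemical"])
        if "capillaries" in ch:
            ch["capillaries"] = np.asarray(ch["capillaries"], dtype=int)
        _apply_fields(cfg.chem, ch, "overrides.chemical")
    if "init" in over:
        init = dict(over["init"])
        if "wound" in init and init["wound"] is not None:
            mask = np.zeros(cfg.grid.shape, dtype=bool)
            for i, j in init["wound"]:
                mask[i, j] = True
            init["wound"] = mask
        cfg.init.update(init)
    if "seed" in doc:
        cfg.num.seed = int(doc["seed"])
    cfg.source = _plain(doc)
    return cfg


def _plain(obj):
    """Recursively convert numpy scalars/arrays for JSON/YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_config(cfg: ScenarioConfig) -> dict:
    """The loadable dict form of a config (the original document when the
    config came from one)."""
    if cfg.source is not None:
        return cfg.source
    return {"example": cfg.name, "seed": cfg.num.seed}


def write_outputs(traj, out_dir: Union[str, Path]) -> dict:
    """Write metrics.csv, snapshot arrays and manifest.json for a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.metrics.to_csv(out / "metrics.csv", index=False)

    snapdir = out / "snapshots"
    snapdir.mkdir(exist_ok=True)
    for istep, u in traj.snapshots.items():
        for i, name in enumerate(traj.cfg.names):
            np.savetxt(snapdir / f"step_{istep:05d}_{name}.txt", u[i])
    sidecar = {"components": list(traj.cfg.names),
               "shape": [int(traj.cfg.grid.nx), int(traj.cfg.grid.ny)],
               "h_mm": traj.cfg.grid.h,
               "steps": sorted(int(s) for s in traj.snapshots)}
    (snapdir / "components.json").write_text(json.dumps(sidecar, indent=1))

    m = traj.metrics
    manifest = {
        "version": _VERSION,
        "config": dump_config(traj.cfg),
        "seed": int(traj.seed),
        "start_step": int(m["step"].iloc[0]),
        "end_step": int(m["step"].iloc[-1]),
        "diagnostics": {
            "total_clamped_mass": float(m["clamped_mass"].sum()),
            "capped_cells_max": int(m["capped_cells"].max()),
            "newton_iters_total": int(m["newton_iters"].sum()),
        },
    }
    (out / "manifest.json").write_text(json.dumps(_plain(manifest), indent=1))
    return manifest


def read_manifest(out_dir: Union[str, Path]) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
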