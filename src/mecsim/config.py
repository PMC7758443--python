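"""Structured YAML configuration: lossless TissueSpec round-trip plus
protocol, solver and ionic-parameter blocks for the command-line interface.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import yaml

from .cell_models.fibroblast import FibroblastParams
from .cell_models.ionic import IonicParams, RemodelingSpec, apply_remodeling
from .cell_models.myofilament import MyofilamentParams, StrainCouplingParams
from .engine.run import SolverConfig
from .fiber import ConductionParams, FiberGeometry
from .protocols import PacingProtocol, StretchProtocol, SweepConfig
from .tissue import FibroblastAttachment, GapJunction, TissueSpec

__all__ = ["spec_to_dict", "spec_from_dict", "load_config", "dump_config"]


def spec_to_dict(spec: TissueSpec) -> dict:
    return {
        "n_cells": spec.n_cells,
        "geometries": [
            {"n_cru": g.n_cru, "resting_SL": np.asarray(g.resting_SL).tolist()}
            for g in spec.geometries
        ],
        "junctions": [
            {"upstream": j.upstream, "downstream": j.downstream, "g_gap": j.g_gap}
            for j in spec.junctions
        ],
        "fibroblasts": [
            {"cell": fb.cell, "cru": fb.cru, "params": asdict(fb.params)}
            for fb in spec.fibroblasts
        ],
        "seeds": dict(spec.seeds),
        "verbatim_junction_signs": spec.verbatim_junction_signs,
        "sarcomere_mode": spec.sarcomere_mode,
    }


def spec_from_dict(d: dict) -> TissueSpec:
    return TissueSpec(
        n_cells=d["n_cells"],
        geometries=[
            FiberGeometry(n_cru=g["n_cru"], resting_SL=np.asarray(g["resting_SL"]))
            for g in d["geometries"]
        ],
        junctions=[GapJunction(**j) for j in d.get("junctions", [])],
        fibroblasts=[
            FibroblastAttachment(cell=f["cell"], cru=f["cru"], params=FibroblastParams(**f["params"]))
            for f in d.get("fibroblasts", [])
        ],
        seeds=dict(d.get("seeds", {})),
        verbatim_junction_signs=d.get("verbatim_junction_signs", False),
        sarcomere_mode=d.get("sarcomere_mode", "relaxed"),
    )


def load_config(path) -> dict:
    """Build simulation objects from a YAML file.

    Returns a dict with keys: spec, stretch, pacing, sweep, solver,
    ionic_params, coupling, myof_params.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}

    if "spec" in cfg:
        spec = spec_from_dict(cfg["spec"])
    else:
        from .tissue import build_tissue_spec

        spec = build_tissue_spec(**cfg.get("tissue", {}))

    stretch = StretchProtocol(**cfg.get("stretch", {}))
    pacing_cfg = dict(cfg.get("pacing", {}))
    conduction = ConductionParams(**pacing_cfg.pop("conduction", {}))
    pacing = PacingProtocol(conduction=conduction, **pacing_cfg)
    sweep = SweepConfig(**cfg.get("sweep", {}))
    solver = SolverConfig(**cfg.get("solver", {}))

    ionic_cfg = dict(cfg.get("ionic", {}))
    remodel = ionic_cfg.pop("remodeling", False)
    ionic = IonicParams(**ionic_cfg)
    if remodel:
        spec_r = RemodelingSpec(**remodel) if isinstance(remodel, dict) else RemodelingSpec()
        ionic = apply_remodeling(ionic, spec_r)
    coupling = StrainCouplingParams(**cfg.get("strain_coupling", {}))
    myof = MyofilamentParams(**cfg.get("myofilament", {}))

    return {
        "spec": spec,
        "stretch": stretch,
        "pacing": pacing,
        "sweep": sweep,
        "solver": solver,
        "ionic_params": ionic,
        "coupling": coupling,
        "myof_params": myof,
    }


def dump_config(spec: TissueSpec, path, **blocks) -> None:
    """Write a config file with the lossless spec block and optional
    stretch/pacing/sweep/solver blocks given as dataclass instances."""
    out = {"spec": spec_to_dict(spec)}
    for k, v in blocks.items():
        out[k] = asdict(v) if not isinstance(v, dict) else v
    with open(path, "w") as f:
        yaml.safe_dump(out, f, sort_keys=False)
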