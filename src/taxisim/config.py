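"""Structured-config I/O and run manifests.

Experiments are fully described by a YAML mapping with sections
``controller`` (an LTI filter or a designed pathway), ``motor``,
``field`` and ``simulation``; :func:`load_config`/:func:`save_config`
round-trip these to :class:`~taxisim.swarm.SimulationConfig`.  Pathway
parameter sets can be exported as TSV for provenance, and every CLI run
writes a JSON manifest tying its outputs to the config snapshot, seed
and package version.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import yaml

from . import __version__
from .fields import ConcentrationField
from .filters import ControllerFilter
from .motor import MotorModel
from .pathways import DesignedPathway, Receptor
from .swarm import SimulationConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config",
           "save_config", "controller_from_dict", "params_to_tsv",
           "write_manifest"]

_FILTER_FIELDS = ("kind", "A", "omega0", "omega1", "omega2", "rank",
                  "sign", "baseline")
_PATHWAY_FIELDS = ("variant", "c_v", "d_v", "k_phos", "k_dephos", "Y_T",
                   "k_auto")
_SIM_FIELDS = ("n_bacteria", "duration", "dt", "speed", "seed",
               "record_stride", "record_positions", "reorientation",
               "reorient_sd", "K_L", "pathway_substeps")


def controller_to_dict(c) -> dict:
    if isinstance(c, ControllerFilter):
        d = {f: getattr(c, f) for f in _FILTER_FIELDS}
        d["type"] = "filter"
        return d
    if isinstance(c, DesignedPathway):
        d = {f: getattr(c, f) for f in _PATHWAY_FIELDS}
        d["type"] = "pathway"
        d["K_L"] = c.receptor.K_L
        return d
    raise TypeError(f"unsupported controller {type(c).__name__}")


def controller_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type", "filter")
    if kind == "filter":
        return ControllerFilter(**{k: v for k, v in d.items()
                                   if k in _FILTER_FIELDS})
    if kind == "pathway":
        receptor = Receptor(K_L=float(d.pop("K_L", 1.0)))
        return DesignedPathway(receptor=receptor,
                               **{k: v for k, v in d.items()
                                  if k in _PATHWAY_FIELDS})
    raise ValueError(f"unknown controller type {kind!r}")


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "controller": controller_to_dict(config.controller),
        "motor": {
            "K_half": config.motor.K_half,
            "hill": config.motor.hill,
            "dt_motor": config.motor.dt_motor,
            "persistence": config.motor.persistence,
        },
        "field": {
            "shape": config.field_.shape,
            "L0": config.field_.L0,
            "r": config.field_.r,
            "offset": list(config.field_.offset),
        },
        "simulation": {
            **{f: getattr(config, f) for f in _SIM_FIELDS},
            "init_position": list(config.init_position),
        },
    }


def config_from_dict(d: dict) -> SimulationConfig:
    sim = dict(d.get("simulation", {}))
    init = tuple(sim.pop("init_position", (1.4, 0.0)))
    fld = dict(d.get("field", {}))
    fld["offset"] = tuple(fld.get("offset", (0.0, 0.0)))
    return SimulationConfig(
        controller=controller_from_dict(d.get("controller", {})),
        motor=MotorModel(**d.get("motor", {})),
        field_=ConcentrationField(**fld),
        init_position=init,
        **{k: v for k, v in sim.items() if k in _SIM_FIELDS},
    )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def params_to_tsv(obj, path) -> None:
    """Export any parameter dataclass as a two-column TSV."""
    rows = []
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            for g in dataclasses.fields(v):
                rows.append((f"{f.name}.{g.name}", getattr(v, g.name)))
        else:
            rows.append((f.name, v))
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


def write_manifest(path, config: SimulationConfig | None, seed,
                   outputs) -> None:
    """JSON manifest: config snapshot, version, seed, timestamp, outputs."""
    manifest = {
        "package": "taxisim",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": config_to_dict(config) if config is not None else None,
        "outputs": [str(Path(p)) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
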