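"""Run configuration and field serialization.

Configs are hierarchical YAML with four optional blocks -- ``params``,
``domain``, ``sim``, ``stimulus`` -- whose defaults reproduce the
wild-type setup (Table-default kinetics, 550 um^2 front-view area, noise
5e-4 uM).  Unknown keys are rejected by name.  Fields round-trip through
NumPy ``.npz`` containers carrying the node values, the domain
descriptor, the time stamp and a JSON manifest (seed, parameter hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field as dfield

import numpy as np
import yaml

from .model import GMParameters
from .domains import RingDomain, SphereDomain, ring_from_front_area, sphere_from_front_area
from .simulate import Field, SimConfig
from .stimuli import StimulusSpec

__all__ = ["RunConfig", "load_config", "save_config", "save_field", "load_field", "params_hash"]

_DOMAIN_KEYS = {"type", "front_area", "n_nodes", "resolution"}


@dataclass
class RunConfig:
    params: GMParameters = dfield(default_factory=GMParameters)
    domain_type: str = "ring"
    front_area: float = 550.0
    n_nodes: int = 256
    resolution: int = 4
    sim: SimConfig = dfield(default_factory=SimConfig)
    stimulus: StimulusSpec | None = None

    def build_domain(self):
        if self.domain_type == "ring":
            return ring_from_front_area(self.front_area, self.n_nodes)
        return sphere_from_front_area(self.front_area, self.resolution)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML run config, applying wild-type defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, {"params", "domain", "sim", "stimulus"}, "config")

    cfg = RunConfig()
    pblock = raw.get("params") or {}
    _check_keys(pblock, set(asdict(GMParameters())), "params")
    try:
        cfg.params = GMParameters(**{**asdict(GMParameters()), **pblock})
    except ValueError as exc:
        raise ValueError(f"invalid params block: {exc}") from exc

    dblock = raw.get("domain") or {}
    _check_keys(dblock, _DOMAIN_KEYS, "domain")
    cfg.domain_type = dblock.get("type", cfg.domain_type)
    if cfg.domain_type not in ("ring", "sphere"):
        raise ValueError(f"domain.type must be ring or sphere, got {cfg.domain_type!r}")
    cfg.front_area = float(dblock.get("front_area", cfg.front_area))
    cfg.n_nodes = int(dblock.get("n_nodes", cfg.n_nodes))
    cfg.resolution = int(dblock.get("resolution", cfg.resolution))

    sblock = raw.get("sim") or {}
    defaults = asdict(SimConfig())
    _check_keys(sblock, set(defaults), "sim")
    cfg.sim = SimConfig(**{**defaults, **sblock})

    stblock = raw.get("stimulus")
    if stblock:
        _check_keys(stblock, {"mode", "pattern", "amplitude"}, "stimulus")
        cfg.stimulus = StimulusSpec(**stblock)
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    doc = {
        "params": asdict(cfg.params),
        "domain": {
            "type": cfg.domain_type,
            "front_area": cfg.front_area,
            "n_nodes": cfg.n_nodes,
            "resolution": cfg.resolution,
        },
        "sim": asdict(cfg.sim),
    }
    if cfg.stimulus is not None:
        doc["stimulus"] = {
            "mode": cfg.stimulus.mode,
            "pattern": cfg.stimulus.pattern,
            "amplitude": cfg.stimulus.amplitude,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def params_hash(params: GMParameters) -> str:
    return hashlib.sha256(json.dumps(asdict(params), sort_keys=True).encode()).hexdigest()[:16]


def save_field(field: Field, path: str, manifest: dict | None = None) -> None:
    dom = field.domain
    descriptor = {"front_area": dom.front_area}
    if isinstance(dom, RingDomain):
        descriptor.update(kind="ring", n_nodes=dom.n_nodes)
    else:
        descriptor.update(kind="sphere", resolution=dom.resolution, n_nodes=dom.n_nodes)
    np.savez(
        path,
        A=field.A,
        H=field.H,
        time=field.time,
        descriptor=json.dumps(descriptor),
        manifest=json.dumps(manifest or {}),
    )


def load_field(path: str):
    """Reconstruct (Field, manifest); shape mismatches raise with detail."""
    data = np.load(path, allow_pickle=False)
    descriptor = json.loads(str(data["descriptor"]))
    if descriptor["kind"] == "ring":
        dom = ring_from_front_area(descriptor["front_area"], descriptor["n_nodes"])
    else:
        dom = sphere_from_front_area(descriptor["front_area"], descriptor["resolution"])
        if dom.n_nodes != descriptor["n_nodes"]:
            raise ValueError(
                f"mesh shape mismatch: file has {descriptor['n_nodes']} nodes, "
                f"rebuilt domain has {dom.n_nodes}"
            )
    A, H = data["A"], data["H"]
    if A.shape != (dom.n_nodes,):
        raise ValueError(f"field shape {A.shape} does not match domain ({dom.n_nodes},)")
    return Field(dom, A, H, float(data["time"])), json.loads(str(data["manifest"]))
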