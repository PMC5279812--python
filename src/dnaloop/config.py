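"""Run configuration: a single human-readable YAML document.

Every output file embeds the sha-256 hash of the canonicalized config and
the package version, so runs are traceable; two runs with an equal config
(and equal seed and worker count 1) produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .looping_analysis import LoopCriteria
from .polymer_core import Protrusion, SimulationParams

__all__ = ["RunConfig", "load_config", "config_hash", "DEFAULTS"]

DEFAULTS = {
    "kind": "floop",
    "seed": 0,
    "n_chains": 100_000,
    "workers": 1,
    "paired_seeds": False,  # variance-reduction extension: share chain proposals
    "params": {},           # SimulationParams overrides
    "criteria": {},         # d_min, epsilon, domega_over_2pi
    "protrusion": None,     # link_index/static position, radius, phase_deg
    "plateau_window": None,
    "trailing_links": 0,
    "confinement_radius": None,
    "log_every": 0,
}


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(_canonical(cfg).encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Validated run configuration; ``raw`` keeps the full document."""

    raw: dict
    kind: str
    seed: int
    n_chains: int
    workers: int
    params: SimulationParams

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        cfg = {**DEFAULTS, **doc}
        kind = cfg["kind"]
        if kind not in ("floop", "eclipse", "eve", "fit", "validate"):
            raise ValueError(f"unknown experiment kind {kind!r}")
        params = SimulationParams(**cfg.get("params", {}))
        return cls(
            raw=cfg,
            kind=kind,
            seed=int(cfg["seed"]),
            n_chains=int(cfg["n_chains"]),
            workers=int(cfg["workers"]),
            params=params,
        )

    def criteria(self) -> LoopCriteria:
        c = self.raw.get("criteria") or {}
        w = self.params.w
        return LoopCriteria(
            d_min=float(c.get("d_min", w)),
            epsilon=float(c.get("epsilon", 2 * w)),
            domega=2 * math.pi * float(c.get("domega_over_2pi", 0.1)),
        )

    def protrusion(self) -> Protrusion | None:
        p = self.raw.get("protrusion")
        if not p:
            return None
        if "position" in p:
            return Protrusion(kind="static", position=p["position"],
                              radius=float(p["radius"]))
        phase = math.radians(float(p.get("phase_deg", 0.0)))
        return Protrusion(kind="on_chain", link_index=int(p["link_index"]),
                          radius=float(p["radius"]), phase=phase)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(doc)
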