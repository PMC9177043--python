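"""YAML configuration for engine runs.

A config file names a potential (built-in family plus parameters), the paths
with their walker arrangements, and the bias/schedule scalars; unspecified
values fall back to the reference protocol defaults.

Example::

    potential:
      name: rotor_flip
      params: {delta_f_hg: 1.0}
    embedding: rolling
    wcf: [1.5, 0.0]
    hg: [-1.5, 0.0]
    total_time: 700
    paths:
      - {mechanism: inside, n_nodes: 11, half_life: inf, attractor_theta: 0.0}
      - {mechanism: outside, n_nodes: 39, half_life: 20.0, attractor_theta: -1.5708}
"""

from __future__ import annotations

import dataclasses
import math

import yaml

from .dynamics import MultiPMDConfig, PathProtocol
from .errors import ParameterError
from .potentials import (
    DoubleChannel2D,
    DoubleWell1D,
    FlatPotential,
    HarmonicWell,
    RotorFlipParams,
    RotorFlipPotential,
)

__all__ = ["config_from_dict", "load_config"]

_POTENTIALS = {
    "rotor_flip": lambda params: RotorFlipPotential(RotorFlipParams(**params)),
    "double_channel": lambda params: DoubleChannel2D(**params),
    "flat": lambda params: FlatPotential(**params),
    "harmonic": lambda params: HarmonicWell(**params),
    "double_well": lambda params: DoubleWell1D(**params),
}


def _half_life(v) -> float:
    if isinstance(v, str) and v.lower() in ("inf", "infinite", "infinity"):
        return math.inf
    return float(v)


def config_from_dict(d: dict) -> MultiPMDConfig:
    d = dict(d)
    pot_spec = d.pop("potential", {"name": "rotor_flip"})
    name = pot_spec.get("name", "rotor_flip")
    if name not in _POTENTIALS:
        raise ParameterError(
            f"unknown potential {name!r}; choose from {sorted(_POTENTIALS)}"
        )
    potential = _POTENTIALS[name](pot_spec.get("params", {}) or {})

    paths = []
    for p in d.pop("paths", None) or [
        {"mechanism": "inside", "n_nodes": 11, "half_life": "inf",
         "attractor_theta": 0.0},
        {"mechanism": "outside", "n_nodes": 39, "half_life": 20.0,
         "attractor_theta": -math.pi / 2},
    ]:
        p = dict(p)
        if "half_life" in p:
            p["half_life"] = _half_life(p["half_life"])
        paths.append(PathProtocol(**p))

    known = {f.name for f in dataclasses.fields(MultiPMDConfig)}
    extra = set(d) - known
    if extra:
        raise ParameterError(f"unknown config keys: {sorted(extra)}")
    if "wcf" in d:
        d["wcf"] = tuple(float(v) for v in d["wcf"])
    if "hg" in d:
        d["hg"] = tuple(float(v) for v in d["hg"])
    return MultiPMDConfig(potential=potential, paths=paths, **d)


def load_config(filename) -> MultiPMDConfig:
    with open(filename) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
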