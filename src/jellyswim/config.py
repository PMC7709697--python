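"""Configuration loading: animal morphology, pulse timing, environment.

Configs are flat JSON or YAML blocks with the keys
d_r, delta_d, h_r, delta_h, h_j (cm), rho_j, rho_w (g/cm^3), C_d,
t_c, t_r (s), freqs (Hz list of measured swimming frequencies) and
animal_id. The measured parameter sets of the two field animals ship as
packaged fixtures ``animal1`` and ``animal2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .geometry import Environment, Morphology
from .kinematics import PulseProgram

__all__ = ["AnimalConfig", "load_config", "load_animal", "dump_config"]

_MORPH_KEYS = ("d_r", "delta_d", "h_r", "delta_h", "h_j")


@dataclass(frozen=True)
class AnimalConfig:
    """One animal's model inputs plus the ambient environment."""

    animal_id: str
    morphology: Morphology
    t_c: float
    t_r: float
    freqs: tuple[float, ...]
    environment: Environment

    def pulse(self, f: float, waveform: str = "cosine") -> PulseProgram:
        return PulseProgram(f=f, t_c=self.t_c, t_r=self.t_r, waveform=waveform)


def _from_mapping(block: dict) -> AnimalConfig:
    missing = [k for k in (*_MORPH_KEYS, "t_c", "t_r") if k not in block]
    if missing:
        raise ValueError(f"config missing keys: {missing}")
    morph = Morphology(
        **{k: float(block[k]) for k in _MORPH_KEYS},
        rho_j=float(block.get("rho_j", 1.024)),
    )
    env = Environment(
        rho_w=float(block.get("rho_w", 1.024)),
        C_d=float(block.get("C_d", 0.42)),
        g_net=float(block.get("g_net", 0.0)),
    )
    return AnimalConfig(
        animal_id=str(block.get("animal_id", "animal")),
        morphology=morph,
        t_c=float(block["t_c"]),
        t_r=float(block["t_r"]),
        freqs=tuple(float(f) for f in block.get("freqs", ())),
        environment=env,
    )


def load_config(path) -> AnimalConfig:
    """Read an animal config from a .json/.yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        block = yaml.safe_load(text)
    else:
        block = json.loads(text)
    if not isinstance(block, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _from_mapping(block)


def load_animal(name: str) -> AnimalConfig:
    """Load a packaged fixture config ('animal1' or 'animal2')."""
    ref = resources.files("jellyswim.data").joinpath(f"{name}.json")
    with resources.as_file(ref) as p:
        if not p.exists():
            raise FileNotFoundError(f"no packaged animal config '{name}'")
        return load_config(p)


def dump_config(cfg: AnimalConfig, path) -> None:
    """Write an animal config as JSON (or YAML by extension)."""
    m = cfg.morphology
    block = {
        "animal_id": cfg.animal_id,
        "d_r": m.d_r,
        "delta_d": m.delta_d,
        "h_r": m.h_r,
        "delta_h": m.delta_h,
        "h_j": m.h_j,
        "rho_j": m.rho_j,
        "rho_w": cfg.environment.rho_w,
        "C_d": cfg.environment.C_d,
        "g_net": cfg.environment.g_net,
        "t_c": cfg.t_c,
        "t_r": cfg.t_r,
        "freqs": list(cfg.freqs),
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(block, sort_keys=False))
    else:
        path.write_text(json.dumps(block, indent=2) + "\n")
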