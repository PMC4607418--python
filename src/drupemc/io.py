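"""Reading simulation configurations (TOML or JSON) and writing summaries.

Config schema::

    [stack]
    n_above = 1.00
    n_below = 1.46
    [[stack.layers]]
    n = 1.337; mua = 0.075; mus = 102.0; g = 0.65; d = 0.03
    [sim]
    photons = 1000000; wth = 1e-4; m = 10; dr = 0.01; dz = 0.01
    nr = 400; na = 90; seed = 1; flesh_layer = 1
    [beam]
    profile = "gaussian"; energy_J = 0.5; radius_cm = 0.05

Only ``stack`` is mandatory; ``sim`` and ``beam`` fall back to defaults.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .optics import Beam, FruitStack, OpticalLayer
from .transport import SimulationConfig

__all__ = ["load_config", "stack_from_dict", "config_from_dict", "beam_from_dict"]


def stack_from_dict(d: dict) -> FruitStack:
    layers = tuple(
        OpticalLayer(
            n=float(lay["n"]),
            mu_a=float(lay["mua"]),
            mu_s=float(lay["mus"]),
            g=float(lay["g"]),
            thickness=float(lay["d"]),
        )
        for lay in d["layers"]
    )
    return FruitStack(
        n_above=float(d.get("n_above", 1.0)),
        layers=layers,
        n_below=float(d.get("n_below", 1.0)),
    )


def config_from_dict(d: dict, n_photons: int | None = None, seed: int | None = None) -> SimulationConfig:
    return SimulationConfig(
        n_photons=int(n_photons if n_photons is not None else d.get("photons", 1_000_000)),
        seed=int(seed if seed is not None else d.get("seed", 0)),
        w_th=float(d.get("wth", 1e-4)),
        roulette_m=float(d.get("m", 10)),
        dr=float(d.get("dr", 0.01)),
        dz=float(d.get("dz", 0.01)),
        nr=int(d.get("nr", 400)),
        nz=int(d["nz"]) if "nz" in d else None,
        na=int(d.get("na", 90)),
        flesh_layer_index=int(d["flesh_layer"]) if "flesh_layer" in d else None,
    )


def beam_from_dict(d: dict) -> Beam:
    return Beam(
        profile=str(d.get("profile", "gaussian")),
        energy=float(d.get("energy_J", 0.5)),
        radius_1e2=float(d.get("radius_cm", 0.05)),
    )


def load_config(path, n_photons: int | None = None, seed: int | None = None):
    """Load a TOML/JSON config; returns (stack, sim_config, beam).

    ``n_photons`` and ``seed`` override the file's values when given.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    if p.suffix.lower() == ".json":
        raw = json.loads(p.read_text())
    else:
        with open(p, "rb") as fh:
            raw = tomllib.load(fh)
    if "stack" not in raw:
        raise ValueError(f"config {p} lacks a [stack] section")
    stack = stack_from_dict(raw["stack"])
    config = config_from_dict(raw.get("sim", {}), n_photons=n_photons, seed=seed)
    beam = beam_from_dict(raw.get("beam", {}))
    return stack, config, beam
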