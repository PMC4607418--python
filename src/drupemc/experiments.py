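"""Scenario runner: stack presets and the standard parameter sweeps.

The presets encode the measured optical properties of a representative
peach at 808 nm (air above; thin highly scattering skin; thick weakly
scattering flesh; stone below, entering only as a refractive boundary).
Scenarios sweep the quantities a fruit-inspection designer cares about —
stone present/absent, skin thickness, flesh thickness, and flesh optical
properties perturbed by +/-20% around their means — and tabulate the energy
budget (diffuse reflectance, per-layer absorption, stone-absorbed fraction)
of each run with Monte Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .convolve import convolve_gaussian
from .optics import Beam, FruitStack, OpticalLayer
from .scoring import SimulationResult
from .transport import SimulationConfig, run_simulation

__all__ = [
    "PEACH_SKIN",
    "PEACH_FLESH",
    "FLESH_OPTICS_GRID",
    "preset_stack",
    "baseline_stack",
    "ScenarioResult",
    "scenario_core_effect",
    "scenario_skin_effect",
    "scenario_flesh_effect",
    "scenario_optics_grid",
    "scenario_angular",
    "normalize_profile",
    "run_cli",
]

# Measured single-peach properties at 808 nm.
PEACH_SKIN = OpticalLayer(n=1.337, mu_a=0.075, mu_s=102.0, g=0.65, thickness=0.03)
PEACH_FLESH = OpticalLayer(n=1.342, mu_a=0.024, mu_s=28.4, g=0.61, thickness=2.34)
_N_AIR = 1.00
_N_STONE = 1.46

#: Flesh (mu_a, mu_s) pairs: the mean and the four +/-20% extremes, 1/cm.
FLESH_OPTICS_GRID: tuple[tuple[float, float], ...] = (
    (0.024, 28.4),
    (0.029, 34.1),
    (0.029, 22.7),
    (0.019, 34.1),
    (0.019, 22.7),
)


def preset_stack(name: str) -> FruitStack:
    """Built-in stacks by name.

    ``"table2"``: the measured skin/flesh/stone peach;
    ``"table2_no_core"``: same with air (n=1.00) below the flesh;
    ``"table2_flesh_only"``: the flesh slab directly under air, stone below.
    """
    if name == "table2":
        return FruitStack(_N_AIR, (PEACH_SKIN, PEACH_FLESH), _N_STONE)
    if name == "table2_no_core":
        return FruitStack(_N_AIR, (PEACH_SKIN, PEACH_FLESH), _N_AIR)
    if name == "table2_flesh_only":
        return FruitStack(_N_AIR, (PEACH_FLESH,), _N_STONE)
    raise KeyError(f"unknown preset {name!r}")


def baseline_stack(
    d1: float = 0.03,
    d2: float = 2.0,
    flesh_mua: float = 0.024,
    flesh_mus: float = 28.4,
    n_below: float = _N_STONE,
) -> FruitStack:
    """Skin/flesh/stone stack with the sweep knobs exposed; the defaults are
    the baseline of the optics grid (skin 0.03 cm, flesh 2.0 cm, mean flesh
    coefficients, stone below)."""
    skin = replace(PEACH_SKIN, thickness=d1)
    flesh = replace(PEACH_FLESH, thickness=d2, mu_a=flesh_mua, mu_s=flesh_mus)
    return FruitStack(_N_AIR, (skin, flesh), n_below)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-run seeds derived reproducibly from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n)


def _totals_row(res: SimulationResult) -> dict:
    row = {
        "Rd_total": res.rd_total,
        "Rd_total_se": res.rd_se,
        "T_core": res.t_below,
        "T_core_se": res.t_below_se,
        "seed": res.config.seed,
    }
    names = ["A_skin", "A_flesh"] if len(res.stack.layers) == 2 else [
        f"A_layer{k}" for k in range(len(res.stack.layers))
    ]
    for k, nm in enumerate(names):
        row[nm] = float(res.a_by_layer[k])
        row[nm + "_se"] = float(res.a_se[k])
    return row


@dataclass
class ScenarioResult:
    """Sweep output: one totals row per run plus the full run results
    (profiles, detection metrics) keyed by the swept values."""

    table: pd.DataFrame
    runs: Mapping[tuple, SimulationResult]


def _sweep(base_config: SimulationConfig, points: Sequence[tuple], make_stack) -> ScenarioResult:
    seeds = _child_seeds(base_config.seed, len(points))
    rows = []
    runs: dict[tuple, SimulationResult] = {}
    for point, s in zip(points, seeds):
        cfg = replace(base_config, seed=int(s))
        res = run_simulation(make_stack(*point), cfg)
        row = dict(zip(_point_names(point), point))
        row.update(_totals_row(res))
        rows.append(row)
        runs[point] = res
    return ScenarioResult(table=pd.DataFrame(rows), runs=runs)


def _point_names(point: tuple) -> list[str]:
    return [f"param{i}" for i in range(len(point))]


def scenario_core_effect(
    config: SimulationConfig, d2_values: Sequence[float] = (1.5, 2.0, 2.5, 3.0)
) -> ScenarioResult:
    """Stone present (n_below=1.46) vs absent (air, 1.00) across flesh
    thicknesses: the stone lowers total reflectance and flesh absorption,
    and the gap shrinks as the flesh thickens."""
    points = [(d2, nb) for nb in (1.00, 1.46) for d2 in d2_values]
    out = _sweep(config, points, lambda d2, nb: baseline_stack(d2=d2, n_below=nb))
    out.table = out.table.rename(columns={"param0": "d2_cm", "param1": "n_below"})
    return out


def scenario_skin_effect(
    config: SimulationConfig,
    d1_values: Sequence[float] = (0.01, 0.03, 0.05),
    d2: float = 1.5,
) -> ScenarioResult:
    """Skin-thickness sweep at fixed flesh thickness: a thicker skin raises
    near-axis reflectance, lowers it at mid range, and lowers the detection
    efficiency close to the incident point."""
    points = [(d1,) for d1 in d1_values]
    out = _sweep(config, points, lambda d1: baseline_stack(d1=d1, d2=d2))
    out.table = out.table.rename(columns={"param0": "d1_cm"})
    return out


def scenario_flesh_effect(
    config: SimulationConfig,
    d2_values: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 3.0),
) -> ScenarioResult:
    """Flesh-thickness sweep: reflectance and flesh absorption rise mildly
    with thickness while the stone-absorbed fraction falls."""
    points = [(d2,) for d2 in d2_values]
    out = _sweep(config, points, lambda d2: baseline_stack(d2=d2))
    out.table = out.table.rename(columns={"param0": "d2_cm"})
    return out


def scenario_optics_grid(config: SimulationConfig) -> ScenarioResult:
    """The five flesh (mu_a, mu_s) combinations (mean and +/-20% extremes)
    at skin 0.03 cm / flesh 2.0 cm: the standard energy-budget grid."""
    out = _sweep(
        config,
        list(FLESH_OPTICS_GRID),
        lambda mua, mus: baseline_stack(flesh_mua=mua, flesh_mus=mus),
    )
    out.table = out.table.rename(columns={"param0": "flesh_mua", "param1": "flesh_mus"})
    return out


def scenario_angular(
    config: SimulationConfig, beam: Beam | None = None
) -> pd.DataFrame:
    """Angularly resolved reflectance of the baseline stack, convolved with
    the Gaussian beam per exit-angle bin; flat across 0-80 degrees with a
    sharp drop in the 80-90 degree bins."""
    if beam is None:
        beam = Beam()
    res = run_simulation(baseline_stack(), config)
    prof = res.angular()  # (nr, na), per launched J
    if beam.profile == "gaussian":
        conv = np.empty_like(prof)
        for j in range(prof.shape[1]):
            conv[:, j] = convolve_gaussian(res.r, prof[:, j], beam).response
    else:
        conv = beam.energy * prof
    r = np.repeat(res.r, res.grids.na)
    alpha = np.tile(res.grids.alpha_centers_deg, res.grids.nr)
    return pd.DataFrame(
        {"r_cm": r, "alpha_deg": alpha, "Rd_per_cm2_per_sr": conv.ravel()}
    )


def normalize_profile(r: np.ndarray, profile: np.ndarray, r_ref: float) -> np.ndarray:
    """Divide a radial profile by its value at the grid point nearest
    ``r_ref`` (e.g. the first experimental source-detector distance), so the
    returned profile is exactly 1 there.  Scale invariant."""
    r = np.asarray(r, dtype=float)
    profile = np.asarray(profile, dtype=float)
    idx = int(np.argmin(np.abs(r - r_ref)))
    if abs(r[idx] - r_ref) > (r[1] - r[0]):
        raise ValueError(f"r_ref={r_ref} is not on the profile grid")
    ref = profile[idx]
    if not np.isfinite(ref) or ref == 0.0:
        raise ValueError(f"profile vanishes at the reference radius {r_ref}")
    return profile / ref


def run_cli(argv: Sequence[str] | None = None) -> int:
    """Command-line entry point (see :mod:`drupemc.cli`)."""
    from .cli import run_cli as _run

    return _run(argv)
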