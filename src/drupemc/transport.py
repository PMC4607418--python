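"""Monte Carlo photon transport through the layered stack.

The hop-drop-spin scheme: a photon is launched straight down with weight
1 - R_sp, hops an exponentially distributed optical step, drops a fraction
mu_a/mu_t of its weight at each interaction, spins into a new direction
sampled from the Henyey-Greenstein phase function, and negotiates layer
boundaries by Snell/Fresnel draws.  Low-weight photons are terminated
unbiasedly by Russian roulette.  The unused dimensionless step is carried
across boundaries and re-scaled by the new layer's mu_t.

``run_simulation`` drives the compiled kernel in :mod:`drupemc._kernel`;
the per-photon operations below wrap the same compiled primitives so unit
tests and the kernel exercise identical formulas.  ``trace_photon`` is a
pure-Python tracer built from those operations, useful at small photon
counts and as a structural cross-check of the kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel
from ._kernel import _fresnel, _hg_cos, _spin
from .optics import FruitStack, OpticalLayer, specular_reflectance
from .scoring import ScoringGrids, SimulationResult, score_escape

__all__ = [
    "Photon",
    "SimulationConfig",
    "BoundaryOutcome",
    "TerminalEvent",
    "launch_photon",
    "sample_step",
    "distance_to_boundary",
    "absorb",
    "scatter",
    "cross_or_reflect",
    "roulette",
    "trace_photon",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    """Run parameters: photon count, roulette settings, grid geometry, seed.

    ``nz`` defaults to ceil(total thickness / dz) at run time (capped for a
    semi-infinite stack); ``na`` defaults to 90 one-degree exit-angle bins.
    ``flesh_layer_index`` marks the layer whose interactions define an
    effective photon; by default layer 1 of a multi-layer (skin/flesh) stack
    or layer 0 of a single-layer stack.
    """

    n_photons: int
    seed: int = 0
    w_th: float = 1e-4
    roulette_m: float = 10.0
    dr: float = 0.01
    dz: float = 0.01
    nr: int = 400
    nz: Optional[int] = None
    na: int = 90
    flesh_layer_index: Optional[int] = None
    max_events: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.w_th < 1.0:
            raise ValueError("w_th must lie in (0, 1)")
        if self.roulette_m <= 1.0:
            raise ValueError("roulette_m must exceed 1")
        if self.dr <= 0 or self.dz <= 0:
            raise ValueError("dr and dz must be positive")
        if min(self.nr, self.na) < 1:
            raise ValueError("nr and na must be >= 1")
        if self.nz is not None and self.nz < 1:
            raise ValueError("nz must be >= 1")

    def resolved_nz(self, stack: FruitStack) -> int:
        if self.nz is not None:
            return self.nz
        total = stack.total_thickness
        if math.isinf(total):
            return 400
        return max(1, int(math.ceil(total / self.dz)))

    def resolved_flesh_index(self, stack: FruitStack) -> int:
        if self.flesh_layer_index is not None:
            return self.flesh_layer_index
        return 1 if len(stack.layers) >= 2 else 0


@dataclass
class Photon:
    """Tracked photon state; z = 0 at the surface, increasing downward."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    layer_index: int = 0
    alive: bool = True
    path_by_layer: np.ndarray = field(default_factory=lambda: np.zeros(1))
    interacted_in_flesh: bool = False
    residual_step: float = 0.0  # dimensionless path carried across boundaries

    @property
    def z(self) -> float:
        return float(self.position[2])


@dataclass(frozen=True)
class BoundaryOutcome:
    """Result of a boundary negotiation: 'reflected', 'entered', or
    'escaped_above' / 'escaped_below' with exit bookkeeping."""

    kind: str
    new_layer: Optional[int] = None
    exit_weight: float = 0.0
    r: float = 0.0
    alpha: float = 0.0


@dataclass(frozen=True)
class TerminalEvent:
    """Terminal record of one traced photon."""

    kind: str  # 'escaped_above' | 'escaped_below' | 'terminated' | 'runaway'
    weight: float
    r: float
    alpha: float
    n_events: int
    interacted_in_flesh: bool
    path_by_layer: np.ndarray
    absorbed_by_layer: np.ndarray


def launch_photon(stack: FruitStack, rng: np.random.Generator) -> Photon:
    """Launch a photon orthogonally into the stack at the origin.

    The initial unit weight is decremented by the deterministic specular
    reflectance of the collimated beam; finite beams are handled afterwards
    by convolving the impulse response, so the launch direction is always
    (0, 0, 1).
    """
    w = 1.0 - specular_reflectance(stack.n_above, stack.layers[0].n)
    return Photon(
        position=np.zeros(3),
        direction=np.array([0.0, 0.0, 1.0]),
        weight=w,
        layer_index=0,
        path_by_layer=np.zeros(len(stack.layers)),
    )


def sample_step(mu_a: float, mu_s: float, rng: np.random.Generator) -> float:
    """Free-path length s = -ln(xi)/(mu_a + mu_s) in cm."""
    mu_t = mu_a + mu_s
    if mu_t <= 0.0:
        raise ValueError("cannot sample a step in a non-interacting layer")
    return float(_kernel._sample_step(mu_t, rng.random()))


def distance_to_boundary(photon: Photon, stack: FruitStack):
    """Distance along the current direction to the layer's bounding plane.

    Returns ``(distance, 'upper'|'lower')``, or ``(None, None)`` when the
    direction is parallel to the planes.
    """
    zb = stack.boundaries
    lay = photon.layer_index
    z = photon.z
    if not (zb[lay] - 1e-12 <= z <= zb[lay + 1] + 1e-12):
        raise RuntimeError(
            f"photon at z={z} outside its recorded layer [{zb[lay]}, {zb[lay + 1]}]"
        )
    uz = float(photon.direction[2])
    if uz > 0.0:
        return (zb[lay + 1] - z) / uz, "lower"
    if uz < 0.0:
        return (zb[lay] - z) / uz, "upper"
    return None, None


def absorb(photon: Photon, layer: OpticalLayer, flesh_layer_index: int = -1) -> float:
    """Deposit dw = w * mu_a/mu_t at the interaction site; returns the
    deposit.  Marks the photon as flesh-interacting when it sits in the
    flesh layer (any interaction counts, even with mu_a = 0)."""
    dw = photon.weight * layer.mu_a / layer.mu_t
    photon.weight -= dw
    if photon.layer_index == flesh_layer_index:
        photon.interacted_in_flesh = True
    return dw


def scatter(photon: Photon, g: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a Henyey-Greenstein deflection and a uniform azimuth, rotate
    the direction, and return the new unit vector."""
    ct = _hg_cos(g, rng.random())
    psi = 2.0 * np.pi * rng.random()
    ux, uy, uz = _spin(*photon.direction, ct, psi)
    photon.direction = np.array([ux, uy, uz])
    return photon.direction


def _refract_cos(n_i: float, n_t: float, ca_i: float) -> float:
    """Cosine of the refraction angle by Snell's law (ca_i = |cos a_i|)."""
    sa_i = math.sqrt(max(0.0, 1.0 - ca_i * ca_i))
    sa_t = min(1.0, n_i * sa_i / n_t)
    return math.sqrt(max(0.0, 1.0 - sa_t * sa_t))


def cross_or_reflect(
    photon: Photon,
    boundary: str,
    stack: FruitStack,
    rng: np.random.Generator,
) -> BoundaryOutcome:
    """Negotiate a boundary the photon is sitting on.

    With probability R(alpha_i) the z-component of the direction is negated;
    otherwise the photon refracts by Snell's law into the adjacent layer or
    escapes into the ambient medium.  On internal crossing the transverse
    direction components are scaled by n_i/n_t (the residual dimensionless
    step needs no explicit rescaling: it is converted with the new layer's
    mu_t on the next hop).
    """
    lay = photon.layer_index
    n_layers = len(stack.layers)
    n_i = stack.layers[lay].n
    going_down = boundary == "lower"
    if going_down:
        n_t = stack.n_below if lay == n_layers - 1 else stack.layers[lay + 1].n
    else:
        n_t = stack.n_above if lay == 0 else stack.layers[lay - 1].n
    uz = float(photon.direction[2])
    ca_i = abs(uz)
    if rng.random() <= _fresnel(n_i, n_t, ca_i):
        photon.direction[2] = -uz
        return BoundaryOutcome("reflected", new_layer=lay)
    ca_t = _refract_cos(n_i, n_t, ca_i)
    x, y = float(photon.position[0]), float(photon.position[1])
    r = math.hypot(x, y)
    alpha = math.acos(min(1.0, ca_t))
    if going_down and lay == n_layers - 1:
        photon.alive = False
        return BoundaryOutcome("escaped_below", exit_weight=photon.weight, r=r, alpha=alpha)
    if not going_down and lay == 0:
        photon.alive = False
        return BoundaryOutcome("escaped_above", exit_weight=photon.weight, r=r, alpha=alpha)
    scale = n_i / n_t
    photon.direction[0] *= scale
    photon.direction[1] *= scale
    photon.direction[2] = ca_t if going_down else -ca_t
    photon.layer_index = lay + 1 if going_down else lay - 1
    return BoundaryOutcome("entered", new_layer=photon.layer_index)


def roulette(
    photon: Photon, w_th: float, m: float, rng: np.random.Generator
) -> Photon:
    """Russian roulette: a photon below the weight threshold survives with
    probability 1/m carrying weight m*w, else dies with nothing scored.
    Unbiased: the expected post-roulette weight equals w."""
    if photon.weight >= w_th:
        return photon
    if rng.random() < 1.0 / m:
        photon.weight *= m
    else:
        photon.alive = False
        photon.weight = 0.0
    return photon


def trace_photon(
    stack: FruitStack,
    config: SimulationConfig,
    rng: np.random.Generator,
    grids: ScoringGrids,
) -> TerminalEvent:
    """Trace one photon with the pure-Python operation pipeline.

    Functionally equivalent to the compiled kernel (same primitives, same
    draw order) but orders of magnitude slower; intended for small photon
    counts and for testing the loop structure itself.
    """
    flesh_idx = config.resolved_flesh_index(stack)
    photon = launch_photon(stack, rng)
    photon.path_by_layer = np.zeros(len(stack.layers))
    absorbed = np.zeros(len(stack.layers))
    zb = stack.boundaries
    events = 0
    kind = "terminated"
    exit_r = 0.0
    exit_alpha = 0.0
    exit_w = 0.0

    while photon.alive:
        events += 1
        if events > config.max_events:
            kind = "runaway"
            photon.alive = False
            break
        lay = stack.layers[photon.layer_index]
        if photon.residual_step <= 0.0:
            xi = rng.random()
            photon.residual_step = -math.log(xi if xi > 0.0 else 1e-12)
        dist, which = distance_to_boundary(photon, stack)
        step = photon.residual_step / lay.mu_t
        if dist is not None and dist * lay.mu_t <= photon.residual_step:
            photon.position += photon.direction * dist
            # snap to the plane to avoid drift
            photon.position[2] = (
                zb[photon.layer_index + 1] if which == "lower" else zb[photon.layer_index]
            )
            photon.path_by_layer[photon.layer_index] += dist
            photon.residual_step -= dist * lay.mu_t
            outcome = cross_or_reflect(photon, which, stack, rng)
            if outcome.kind == "escaped_above":
                kind = "escaped_above"
                exit_r, exit_alpha, exit_w = outcome.r, outcome.alpha, outcome.exit_weight
                score_escape(
                    grids, exit_r, exit_alpha, exit_w,
                    photon.interacted_in_flesh, photon.path_by_layer,
                )
            elif outcome.kind == "escaped_below":
                kind = "escaped_below"
                exit_r, exit_alpha, exit_w = outcome.r, outcome.alpha, outcome.exit_weight
                ir = min(int(exit_r / grids.dr), grids.nr - 1)
                if exit_r >= grids.nr * grids.dr:
                    grids.overflow_below[0] += exit_w
                grids.below_r[ir] += exit_w
            continue
        photon.position += photon.direction * step
        photon.path_by_layer[photon.layer_index] += step
        photon.residual_step = 0.0
        dw = absorb(photon, lay, flesh_idx)
        absorbed[photon.layer_index] += dw
        ir = min(int(math.hypot(photon.position[0], photon.position[1]) / grids.dr), grids.nr - 1)
        iz = min(max(int(photon.z / grids.dz), 0), grids.nz - 1)
        grids.absorb_r_z[ir, iz] += dw
        if photon.weight <= 0.0:  # fully absorbed: nothing left to trace
            photon.alive = False
            continue
        scatter(photon, lay.g, rng)
        roulette(photon, config.w_th, config.roulette_m, rng)

    grids.n_launched += 1
    return TerminalEvent(
        kind=kind,
        weight=exit_w,
        r=exit_r,
        alpha=exit_alpha,
        n_events=events,
        interacted_in_flesh=photon.interacted_in_flesh,
        path_by_layer=photon.path_by_layer.copy(),
        absorbed_by_layer=absorbed,
    )


def run_simulation(
    stack: FruitStack,
    config: SimulationConfig,
    beam=None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the full simulation with the compiled kernel.

    Launches ``config.n_photons`` photons from one seeded generator
    (``config.seed`` unless an explicit ``rng`` is supplied), aggregates the
    scoring grids and returns totals with Monte Carlo standard errors.
    Identical (seed, config, stack) reproduce bit-identical results.
    """
    nz = config.resolved_nz(stack)
    flesh_idx = config.resolved_flesh_index(stack)
    grids = ScoringGrids(
        dr=config.dr, dz=config.dz, nr=config.nr, nz=nz, na=config.na,
        flesh_layer_index=flesh_idx,
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_l = np.array([lay.n for lay in stack.layers])
    mua_l = np.array([lay.mu_a for lay in stack.layers])
    mus_l = np.array([lay.mu_s for lay in stack.layers])
    g_l = np.array([lay.g for lay in stack.layers])
    zb = stack.boundaries

    rd_sum, rd_sq, tb_sum, tb_sq, a_sum, a_sq, n_runaway = _kernel._run_kernel(
        config.n_photons,
        stack.n_above,
        stack.n_below,
        n_l,
        mua_l,
        mus_l,
        g_l,
        zb,
        flesh_idx,
        config.w_th,
        config.roulette_m,
        config.max_events,
        rng,
        config.dr,
        config.dz,
        config.nr,
        nz,
        config.na,
        grids.refl_r_alpha,
        grids.absorb_r_z,
        grids.below_r,
        grids.eff_weight_r,
        grids.total_weight_r,
        grids.eff_count_r,
        grids.total_count_r,
        grids.flesh_path_r,
        grids.total_path_r,
        grids.overflow_refl_alpha,
        grids.overflow_below,
    )
    n = config.n_photons
    grids.n_launched = n

    def _mean_se(total, total_sq):
        mean = total / n
        var = max(0.0, total_sq / n - mean * mean)
        return mean, math.sqrt(var / n)

    rd_total, rd_se = _mean_se(rd_sum, rd_sq)
    t_below, t_se = _mean_se(tb_sum, tb_sq)
    a_mean = np.empty(len(stack.layers))
    a_se = np.empty(len(stack.layers))
    for k in range(len(stack.layers)):
        a_mean[k], a_se[k] = _mean_se(a_sum[k], a_sq[k])

    return SimulationResult(
        stack=stack,
        config=replace(config, nz=nz, flesh_layer_index=flesh_idx),
        grids=grids,
        r_sp=specular_reflectance(stack.n_above, stack.layers[0].n),
        rd_total=rd_total,
        a_by_layer=a_mean,
        t_below=t_below,
        rd_se=rd_se,
        a_se=a_se,
        t_below_se=t_se,
        n_runaway=n_runaway,
        beam=beam,
    )
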