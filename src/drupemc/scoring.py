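"""Scoring grids, profile normalization and detection-efficiency statistics.

Escaping photon weight is binned on a radial/angular grid at the surface and
absorbed weight on a radial/depth grid inside the tissue.  From the grids
this module derives:

* the radial diffuse-reflectance profile Rd(r) per unit surface area,
* the angularly resolved reflectance per unit area perpendicular to the
  photon direction per steradian,
* the percentage of "effective" photons P_eff(r) — detected photons that
  interacted at least once in the flesh layer — and
* the flesh detection sensitivity S_flesh(r) — the fraction of detected
  optical pathlength spent in the flesh.

P_eff and S_flesh are weight-based by default so roulette-survivor photons
contribute proportionally; a raw-count variant of P_eff is available for
comparison.  Both are ratios, hence invariant to the photon-count scale and
to beam convolution (they are defined on the impulse response).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .optics import Beam, FruitStack
    from .transport import SimulationConfig

__all__ = [
    "ScoringGrids",
    "DetectionMetrics",
    "SimulationResult",
    "score_escape",
    "detection_efficiency",
    "flesh_sensitivity",
    "angular_profile",
    "radial_profile",
]


@dataclass
class ScoringGrids:
    """Accumulators shared by the tracing kernel.

    Radial bins are half-open [k*dr, (k+1)*dr); escapes beyond the grid
    collapse into the last bin and are additionally tracked in the overflow
    accumulators so per-area profiles can exclude them.
    """

    dr: float
    dz: float
    nr: int
    nz: int
    na: int
    flesh_layer_index: int
    refl_r_alpha: np.ndarray = field(repr=False, default=None)
    absorb_r_z: np.ndarray = field(repr=False, default=None)
    below_r: np.ndarray = field(repr=False, default=None)
    eff_weight_r: np.ndarray = field(repr=False, default=None)
    total_weight_r: np.ndarray = field(repr=False, default=None)
    eff_count_r: np.ndarray = field(repr=False, default=None)
    total_count_r: np.ndarray = field(repr=False, default=None)
    flesh_path_r: np.ndarray = field(repr=False, default=None)
    total_path_r: np.ndarray = field(repr=False, default=None)
    overflow_refl_alpha: np.ndarray = field(repr=False, default=None)
    overflow_below: np.ndarray = field(repr=False, default=None)
    n_launched: int = 0

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.dz <= 0:
            raise ValueError("dr and dz must be positive")
        if min(self.nr, self.nz, self.na) < 1:
            raise ValueError("nr, nz, na must be >= 1")
        if self.refl_r_alpha is None:
            self.refl_r_alpha = np.zeros((self.nr, self.na))
        if self.absorb_r_z is None:
            self.absorb_r_z = np.zeros((self.nr, self.nz))
        for name in (
            "below_r",
            "eff_weight_r",
            "total_weight_r",
            "eff_count_r",
            "total_count_r",
            "flesh_path_r",
            "total_path_r",
        ):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.nr))
        if self.overflow_refl_alpha is None:
            self.overflow_refl_alpha = np.zeros(self.na)
        if self.overflow_below is None:
            self.overflow_below = np.zeros(1)

    # -- bin geometry -----------------------------------------------------
    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def alpha_edges(self) -> np.ndarray:
        """Exit-angle bin edges in radians, spanning [0, pi/2]."""
        return np.linspace(0.0, np.pi / 2.0, self.na + 1)

    @property
    def alpha_centers_deg(self) -> np.ndarray:
        edges = np.degrees(self.alpha_edges)
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class DetectionMetrics:
    """Detection efficiency at one radial bin: P_eff in percent, S_flesh as
    a fraction, and the bin-center radius in cm."""

    r: float
    p_eff: float
    s_flesh: float


def score_escape(
    grids: ScoringGrids,
    r: float,
    alpha: float,
    weight: float,
    interacted_in_flesh: bool,
    path_by_layer: np.ndarray,
) -> ScoringGrids:
    """Score one escape through the top surface into the grids.

    Mirrors the kernel's inline scoring; used by the pure-Python tracer and
    for constructing synthetic escape fields in tests.
    """
    if weight < 0.0:
        raise ValueError("escape weight must be non-negative")
    if not (np.isfinite(r) and np.isfinite(alpha)):
        raise ValueError("r and alpha must be finite")
    ia = min(int(alpha / (np.pi / 2.0 / grids.na)), grids.na - 1)
    ir = int(r / grids.dr)
    if ir >= grids.nr:
        ir = grids.nr - 1
        grids.overflow_refl_alpha[ia] += weight
    grids.refl_r_alpha[ir, ia] += weight
    grids.total_weight_r[ir] += weight
    grids.total_count_r[ir] += 1.0
    if interacted_in_flesh:
        grids.eff_weight_r[ir] += weight
        grids.eff_count_r[ir] += 1.0
    path = np.asarray(path_by_layer, dtype=float)
    l_total = float(path.sum())
    idx = grids.flesh_layer_index
    l_flesh = float(path[idx]) if 0 <= idx < path.size else 0.0
    grids.total_path_r[ir] += weight * l_total
    grids.flesh_path_r[ir] += weight * l_flesh
    return grids


def detection_efficiency(grids: ScoringGrids, by_counts: bool = False) -> np.ndarray:
    """P_eff per radial bin, percent: 100 * effective / total detected.

    Weight-based by default; ``by_counts=True`` uses raw photon counts.
    Bins with no detected weight are NaN (undefined, not zero).
    """
    num = grids.eff_count_r if by_counts else grids.eff_weight_r
    den = grids.total_count_r if by_counts else grids.total_weight_r
    out = np.full(grids.nr, np.nan)
    occupied = den > 0
    # clip: accumulation rounding can push the ratio a few ulp past 100
    out[occupied] = np.clip(100.0 * num[occupied] / den[occupied], 0.0, 100.0)
    return out


def flesh_sensitivity(grids: ScoringGrids) -> np.ndarray:
    """S_flesh per radial bin: pooled weighted flesh pathlength over pooled
    weighted total pathlength.  NaN where no pathlength was detected."""
    out = np.full(grids.nr, np.nan)
    occupied = grids.total_path_r > 0
    out[occupied] = np.clip(
        grids.flesh_path_r[occupied] / grids.total_path_r[occupied], 0.0, 1.0
    )
    return out


def radial_profile(grids: ScoringGrids) -> np.ndarray:
    """Diffuse reflectance per unit surface area, 1/cm^2 per launched photon.

    Bin weight divided by (n_launched * annulus area 2 pi r dr); overflow
    weight parked in the last bin is excluded here (it has no defined area)
    though it still counts toward the reflectance total.
    """
    if grids.n_launched <= 0:
        raise ValueError("grids have no launched photons recorded")
    w_r = grids.refl_r_alpha.sum(axis=1).copy()
    w_r[-1] -= grids.overflow_refl_alpha.sum()
    area = 2.0 * np.pi * grids.r_centers * grids.dr
    return w_r / (grids.n_launched * area)


def angular_profile(grids: ScoringGrids, config: "SimulationConfig | None" = None) -> np.ndarray:
    """Reflected energy per unit perpendicular area per steradian, vs (r, alpha).

    Bin weight / (n_launched * 2 pi r dr * cos(alpha) * solid angle of the
    alpha bin), with bin-center radius and angle; units 1/cm^2/sr per
    launched photon.  Overflow weight is excluded from the last radial bin.
    """
    if grids.n_launched <= 0:
        raise ValueError("grids have no launched photons recorded")
    w = grids.refl_r_alpha.copy()
    w[-1, :] -= grids.overflow_refl_alpha
    edges = grids.alpha_edges
    solid = 2.0 * np.pi * (np.cos(edges[:-1]) - np.cos(edges[1:]))  # (na,)
    cos_centers = np.cos(0.5 * (edges[:-1] + edges[1:]))
    area = 2.0 * np.pi * grids.r_centers * grids.dr  # (nr,)
    denom = grids.n_launched * np.outer(area, cos_centers * solid)
    return w / denom


@dataclass
class SimulationResult:
    """Totals, profiles and detection metrics of one Monte Carlo run.

    Totals are fractions of launched energy: specular reflectance ``r_sp``
    (deterministic, excluded from ``rd_total``), total diffuse reflectance
    ``rd_total``, absorbed fraction per layer ``a_by_layer``, and the
    below-escape fraction ``t_below`` (energy crossing into the stone, never
    returning).  Standard errors are Monte Carlo SEs of the per-photon means.
    """

    stack: "FruitStack"
    config: "SimulationConfig"
    grids: ScoringGrids
    r_sp: float
    rd_total: float
    a_by_layer: np.ndarray
    t_below: float
    rd_se: float
    a_se: np.ndarray
    t_below_se: float
    n_runaway: int = 0
    beam: "Beam | None" = None

    @property
    def n_photons(self) -> int:
        return self.grids.n_launched

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def energy_budget_residual(self) -> float:
        """1 - (R_sp + Rd + sum A + T_below); roulette noise, ~N^-1/2."""
        return 1.0 - (self.r_sp + self.rd_total + float(self.a_by_layer.sum()) + self.t_below)

    # -- profiles ---------------------------------------------------------
    @property
    def r(self) -> np.ndarray:
        return self.grids.r_centers

    def radial_reflectance(self) -> np.ndarray:
        return radial_profile(self.grids)

    def p_eff(self, by_counts: bool = False) -> np.ndarray:
        return detection_efficiency(self.grids, by_counts=by_counts)

    def s_flesh(self) -> np.ndarray:
        return flesh_sensitivity(self.grids)

    def angular(self) -> np.ndarray:
        return angular_profile(self.grids, self.config)

    # -- tabular output ---------------------------------------------------
    def totals_frame(self) -> pd.DataFrame:
        rows = [
            ("R_sp", self.r_sp, 0.0),
            ("Rd_total", self.rd_total, self.rd_se),
        ]
        for k in range(len(self.stack.layers)):
            rows.append((f"A_layer{k}", float(self.a_by_layer[k]), float(self.a_se[k])))
        rows.append(("T_below", self.t_below, self.t_below_se))
        rows.append(("budget_residual", self.energy_budget_residual, float("nan")))
        return pd.DataFrame(rows, columns=["quantity", "value", "stderr"])

    def radial_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_cm": self.r,
                "Rd_per_cm2": self.radial_reflectance(),
                "Peff_percent": self.p_eff(),
                "Sflesh": self.s_flesh(),
            }
        )

    def angular_frame(self) -> pd.DataFrame:
        prof = self.angular()
        r = np.repeat(self.r, self.grids.na)
        alpha = np.tile(self.grids.alpha_centers_deg, self.grids.nr)
        return pd.DataFrame(
            {"r_cm": r, "alpha_deg": alpha, "Rd_per_cm2_per_sr": prof.ravel()}
        )

    def absorption_frame(self) -> pd.DataFrame:
        vol = (
            2.0 * np.pi * self.grids.r_centers[:, None] * self.grids.dr * self.grids.dz
        )
        dens = self.grids.absorb_r_z / (self.grids.n_launched * vol)
        r = np.repeat(self.grids.r_centers, self.grids.nz)
        z = np.tile(self.grids.z_centers, self.grids.nr)
        return pd.DataFrame({"r_cm": r, "z_cm": z, "A_per_cm3": dens.ravel()})

    def to_csv(self, outdir) -> None:
        """Write radial.csv, angular.csv, absorption.csv and totals.csv."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.radial_frame().to_csv(out / "radial.csv", index=False)
        self.angular_frame().to_csv(out / "angular.csv", index=False)
        self.absorption_frame().to_csv(out / "absorption.csv", index=False)
        self.totals_frame().to_csv(out / "totals.csv", index=False)

    def summary_dict(self) -> dict:
        return {
            "n_photons": self.n_photons,
            "seed": self.config.seed,
            "R_sp": self.r_sp,
            "Rd_total": self.rd_total,
            "Rd_total_se": self.rd_se,
            "A_by_layer": [float(a) for a in self.a_by_layer],
            "A_by_layer_se": [float(a) for a in self.a_se],
            "T_below": self.t_below,
            "T_below_se": self.t_below_se,
            "budget_residual": self.energy_budget_residual,
            "n_runaway": self.n_runaway,
        }
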