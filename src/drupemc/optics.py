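"""Domain types for the layered fruit stack plus closed-form optics.

The fruit is modeled as a stack of homogeneous plane-parallel slabs
(typically skin over flesh) bounded above by air and below by the stone,
which enters only as a refractive-index boundary condition.  Alongside the
types this module provides the Fresnel/Snell closed forms used at every
boundary crossing and diffusion-theory analytics (effective attenuation,
penetration depth, layered Beer-Lambert attenuation).  The analytics are a
companion to the Monte Carlo kernel, never used inside it.

Units: lengths in cm, absorption/scattering coefficients in 1/cm, energies
in J; refractive indices and the anisotropy factor are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401 (replace re-exported)

import numpy as np

from ._kernel import _fresnel

#: Marker for a layer of unbounded depth.
SEMI_INFINITE = math.inf

__all__ = [
    "SEMI_INFINITE",
    "OpticalLayer",
    "FruitStack",
    "Beam",
    "DiffusionSummary",
    "fresnel_reflectance",
    "specular_reflectance",
    "effective_attenuation",
    "penetration_depth",
    "layered_attenuation",
    "diffusion_summary",
]


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous slab: refractive index, mu_a, mu_s (1/cm), anisotropy
    factor g, and thickness in cm (``SEMI_INFINITE`` for an unbounded slab)."""

    n: float
    mu_a: float
    mu_s: float
    g: float
    thickness: float

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.mu_a < 0.0 or self.mu_s < 0.0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if self.mu_a + self.mu_s <= 0.0:
            raise ValueError("mu_a + mu_s must be positive")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"anisotropy factor must lie in [-1, 1], got {self.g}")
        if not self.thickness > 0.0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (1/cm)."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / mu_t."""
        return self.mu_s / self.mu_t

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient (1 - g) * mu_s (1/cm)."""
        return (1.0 - self.g) * self.mu_s

    @property
    def mu_eff(self) -> float:
        """Diffusion-theory effective attenuation coefficient (1/cm)."""
        return effective_attenuation(self.mu_a, self.mu_s, self.g)


@dataclass(frozen=True)
class FruitStack:
    """Ordered layers (top to bottom) with ambient refractive indices.

    ``n_below`` models the medium under the last layer; for a stone fruit it
    is the stone's index, so the stone acts purely as a Fresnel boundary.
    """

    n_above: float
    layers: tuple[OpticalLayer, ...]
    n_below: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if self.n_above < 1.0 or self.n_below < 1.0:
            raise ValueError("ambient refractive indices must be >= 1")
        for lay in self.layers[:-1]:
            if math.isinf(lay.thickness):
                raise ValueError("only the last layer may be semi-infinite")

    @property
    def boundaries(self) -> np.ndarray:
        """Depths of the n_layers + 1 boundary planes, z=0 at the surface."""
        return np.concatenate(([0.0], np.cumsum([lay.thickness for lay in self.layers])))

    @property
    def total_thickness(self) -> float:
        return float(sum(lay.thickness for lay in self.layers))

    def with_layer(self, index: int, **changes) -> "FruitStack":
        """Copy of the stack with one layer's fields replaced."""
        layers = list(self.layers)
        layers[index] = replace(layers[index], **changes)
        return replace(self, layers=tuple(layers))


@dataclass(frozen=True)
class Beam:
    """Source description: an impulse ('pencil') beam or a Gaussian beam of
    given total energy (J) and 1/e^2 irradiance radius (cm)."""

    profile: str = "gaussian"
    energy: float = 0.5
    radius_1e2: float = 0.05

    def __post_init__(self) -> None:
        if self.profile not in ("pencil", "gaussian"):
            raise ValueError(f"unknown beam profile {self.profile!r}")
        if self.energy <= 0.0:
            raise ValueError("beam energy must be positive")
        if self.profile == "gaussian" and self.radius_1e2 <= 0.0:
            raise ValueError("gaussian beam needs a positive 1/e^2 radius")


@dataclass(frozen=True)
class DiffusionSummary:
    """Diffusion-theory summary of a stack's dominant (flesh) layer."""

    mu_eff: float
    penetration_depth_1pct: float
    boundary_fraction: float


def fresnel_reflectance(n_i: float, n_t: float, cos_alpha_i: float) -> float:
    """Unpolarized Fresnel reflection probability at a planar interface.

    ``cos_alpha_i`` is the cosine of the incidence angle measured from the
    interface normal.  Returns exactly 1 at and beyond the critical angle and
    the analytic normal-incidence limit ((n_i-n_t)/(n_i+n_t))**2 as
    cos_alpha_i -> 1, where the sine/tangent form degenerates to 0/0.
    """
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_alpha_i <= 1.0:
        raise ValueError(f"cos_alpha_i must lie in [0, 1], got {cos_alpha_i}")
    return float(_fresnel(n_i, n_t, cos_alpha_i))


def specular_reflectance(n_above: float, n_first_layer: float) -> float:
    """Normal-incidence specular loss of the collimated beam at the surface."""
    if n_above < 1.0 or n_first_layer < 1.0:
        raise ValueError("refractive indices must be >= 1")
    rn = (n_above - n_first_layer) / (n_above + n_first_layer)
    return rn * rn


def effective_attenuation(mu_a: float, mu_s: float, g: float) -> float:
    """Effective attenuation coefficient sqrt(3 mu_a (mu_a + mu_s')) in 1/cm,
    with mu_s' = (1 - g) mu_s the reduced scattering coefficient."""
    if mu_a < 0.0 or mu_s < 0.0:
        raise ValueError("coefficients must be non-negative")
    if not -1.0 <= g <= 1.0:
        raise ValueError("anisotropy factor must lie in [-1, 1]")
    mu_s_red = (1.0 - g) * mu_s
    return math.sqrt(3.0 * mu_a * (mu_a + mu_s_red))


def penetration_depth(mu_eff: float, fraction: float = 0.01) -> float:
    """Depth (cm) at which deep fluence decays to ``fraction`` of incident,
    -ln(fraction)/mu_eff.  The default 1% level is the conventional
    penetration depth used when sizing fruit-inspection geometries."""
    if mu_eff <= 0.0:
        raise ValueError("penetration depth undefined for mu_eff <= 0")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    return -math.log(fraction) / mu_eff


def layered_attenuation(stack: FruitStack, depth: float) -> float:
    """Diffusion-theory fraction of intensity surviving to ``depth`` (cm).

    Product over traversed layers of exp(-mu_eff,layer * path-in-layer) at
    normal incidence; an analytic stand-in for how much light reaches e.g.
    the distal flesh boundary, never used inside the Monte Carlo kernel.
    """
    if depth < 0.0:
        raise ValueError("depth must be non-negative")
    if depth > stack.total_thickness:
        raise ValueError("depth exceeds the stack's total thickness")
    remaining = depth
    atten = 1.0
    for lay in stack.layers:
        if remaining <= 0.0:
            break
        d_in = min(remaining, lay.thickness)
        atten *= math.exp(-lay.mu_eff * d_in)
        remaining -= d_in
    return atten


def diffusion_summary(
    stack: FruitStack, flesh_layer_index: int = -1, boundary_depth: float | None = None
) -> DiffusionSummary:
    """Summarize a stack's diffusion analytics.

    ``flesh_layer_index`` selects the layer whose mu_eff and 1% penetration
    depth are reported (default: the last layer).  ``boundary_depth`` is the
    depth whose surviving fraction is reported; default is the bottom of the
    stack (the distal flesh boundary for a skin/flesh stack).
    """
    lay = stack.layers[flesh_layer_index]
    mu_eff = lay.mu_eff
    depth = stack.total_thickness if boundary_depth is None else boundary_depth
    return DiffusionSummary(
        mu_eff=mu_eff,
        penetration_depth_1pct=penetration_depth(mu_eff, 0.01) if mu_eff > 0 else math.inf,
        boundary_fraction=layered_attenuation(stack, depth),
    )
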