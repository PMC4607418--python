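"""Convolution of radially symmetric impulse responses with a Gaussian beam.

The Monte Carlo kernel computes the response to an infinitely narrow beam
(per launched joule).  For a Gaussian source of total energy E and 1/e^2
radius R the response at radius r is

    C(r) = (4 E / R^2) * Int_0^inf r' G(r') exp(-2 (r^2 + r'^2)/R^2)
                                       * I_0(4 r r' / R^2) dr'

where G is the impulse response density (1/cm^2 per J) and I_0 the modified
Bessel function.  The product exp(...) * I_0(...) is evaluated as
exp(-2 (r - r')^2 / R^2) * i0e(4 r r'/R^2) with the exponentially scaled
Bessel ``scipy.special.i0e`` — the naive I_0 overflows once r r' >> R^2.
Quadrature is trapezoidal on a refined uniform grid (the tabulated profile
is linearly interpolated); the kernel's exp(-2 (r-r')^2/R^2) factor bounds
the tails, so contributions below ~1e-12 of the peak are negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.special import i0e

from .optics import Beam

__all__ = ["ConvolvedProfile", "convolve_gaussian"]


@dataclass(frozen=True)
class ConvolvedProfile:
    """Beam-convolved radial response: energy density (J/cm^2) on ``r``."""

    r: np.ndarray
    response: np.ndarray
    beam: Beam

    def total_energy(self) -> float:
        """Integrated energy 2 pi Int r C(r) dr over the tabulated grid."""
        return float(np.trapezoid(2.0 * np.pi * self.r * self.response, self.r))


def convolve_gaussian(
    r: np.ndarray, impulse_profile: np.ndarray, beam: Beam
) -> ConvolvedProfile:
    """Convolve a per-launched-joule radial density with a Gaussian beam.

    ``r`` must be a uniform radial grid (cm) and ``impulse_profile`` the
    impulse-response density on it (1/cm^2 per J).  A pencil beam is the
    identity up to the energy scale.  Linear in the profile, positivity
    preserving, and energy conserving: the integrated output equals
    E times the integrated input (up to quadrature tolerance ~0.1%).
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(impulse_profile, dtype=float)
    if r.ndim != 1 or r.shape != g.shape or r.size < 2:
        raise ValueError("r and impulse_profile must be matching 1-D arrays")
    dr = np.diff(r)
    if not np.allclose(dr, dr[0], rtol=1e-6, atol=1e-12):
        raise ValueError("impulse profile must be tabulated on a uniform grid")
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("impulse profile must be finite and non-negative")

    if beam.profile == "pencil":
        return ConvolvedProfile(r=r.copy(), response=beam.energy * g, beam=beam)

    radius = beam.radius_1e2
    energy = beam.energy
    # Refine the quadrature grid: step well below both the tabulation step
    # and the beam radius, so the exp(-2(r-r')^2/R^2) kernel is resolved.
    h = min(dr[0] / 4.0, radius / 20.0)
    rp = np.arange(0.0, r[-1] + h / 2.0, h)
    # Linear interpolation keeps the operator exactly linear in the profile
    # and positivity-preserving; its O((dr/width)^2) bias stays well inside
    # the quadrature tolerance for profiles resolved by the tabulation.
    gp = np.interp(rp, r, g)
    # kernel matrix: exp(-2 (r - r')^2 / R^2) * i0e(4 r r' / R^2)
    diff = r[:, None] - rp[None, :]
    kern = np.exp(-2.0 * diff * diff / (radius * radius)) * i0e(
        4.0 * r[:, None] * rp[None, :] / (radius * radius)
    )
    integrand = kern * (rp * gp)[None, :]
    response = (4.0 * energy / (radius * radius)) * simpson(integrand, x=rp, axis=1)
    return ConvolvedProfile(r=r.copy(), response=response, beam=beam)
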