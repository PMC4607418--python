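# Methods

## The physical model

Stone fruit is treated as a stack of homogeneous plane-parallel slabs with
smooth interfaces, indexed top to bottom, bounded above by air and below by
the stone. Only the slabs are traced; the stone is a pure boundary
condition: a photon that Fresnel-refracts through the distal flesh plane
into the higher-index medium below is scored as "stone absorbed" and never
re-enters. This deliberately ignores any diffuse remission from the woody
endocarp itself — the stone's effect is restricted to what its refractive
mismatch does at the flesh boundary. The geometry is radially symmetric
about the injection axis, so all scoring is in (r, z) and (r, exit angle).

Transport is the standard weighted packet scheme for layered turbid media:

* **Hop.** Dimensionless step `−ln(ξ)` converted by the local
  `μ_t = μ_a + μ_s`. When a boundary interrupts a step, the *unused
  dimensionless* fraction is carried across and converted with the next
  layer's `μ_t` — the carry-over convention, not resampling.
* **Drop.** Deposit `Δw = w·μ_a/μ_t` at each interaction site, binned on
  the (r, z) absorption grid.
* **Spin.** Deflection cosine from the Henyey–Greenstein distribution
  (closed-form inverse CDF; the `g = 0` branch is `2ξ−1`), azimuth uniform
  on [0, 2π) — the phase function is axially symmetric, so the uniform
  azimuth is implied rather than an independent assumption. The direction
  update is the standard spherical rotation with a dedicated branch for
  |u_z| > 1−10⁻⁵, where the generic formula loses precision.
* **Boundary.** Unpolarized Fresnel reflectance decides reflection vs
  crossing by a single uniform draw. The sine/tangent form is 0/0 at normal
  incidence and ill-conditioned at grazing; both are replaced by their
  analytic limits (((n_i−n_t)/(n_i+n_t))² and 1). At and beyond the
  critical angle the reflectance is exactly 1.
* **Termination.** Escape through either ambient boundary, or Russian
  roulette once `w < w_th`: survive with probability 1/m at weight m·w.
  Roulette is unbiased, so the energy budget closes in expectation; the
  residual of a finite run shrinks as N^(−1/2). A packet that loses its
  entire weight in one deposit (possible only when μ_s = 0) is terminated
  directly. A 10⁷-event cap guards against degenerate configurations.

Totals are fractions of launched energy: specular `R_sp` (deterministic,
reported separately and *excluded* from the diffuse total — the only
convention under which the energy budget R_sp + Rd + ΣA + T closes),
diffuse reflectance `Rd_total`, per-layer absorbed fractions, and the
below-escape (stone-absorbed) fraction. Monte Carlo standard errors come
from per-photon first and second moments.

## Detection-efficiency statistics

Fruit graders care about the flesh, but every detected photon crossed the
skin twice. Two per-radial-bin statistics quantify how informative the
detected light is:

* `P_eff(r)`: percentage of detected light that interacted (had at least
  one drop event) in the flesh layer. Weights, not raw counts, are
  accumulated so roulette survivors contribute proportionally; a count
  toggle exists for comparison. A geometric crossing without an interaction
  does not count.
* `S_flesh(r)`: pooled ratio Σw·l_flesh / Σw·l_total of weighted
  geometric pathlengths of detected photons. The pooled ratio (rather than
  a mean of per-photon ratios) is stable in sparsely occupied bins.

Both are scale-free ratios, invariant to photon count and to beam
convolution, so they are always computed on the impulse response.

## Source model and convolution

The kernel's impulse response assumes an infinitely narrow normal-incidence
beam. Responses to a Gaussian beam of energy E and 1/e² radius R follow by
radial convolution,

    C(r) = (4E/R²) ∫ r′ G(r′) exp(−2(r²+r′²)/R²) I₀(4rr′/R²) dr′,

evaluated as exp(−2(r−r′)²/R²)·i0e(4rr′/R²) with the exponentially scaled
Bessel function — the unscaled I₀ overflows once rr′ ≫ R². Quadrature is
Simpson's rule on a grid refined to min(dr/4, R/20), with the tabulated
profile linearly interpolated. Linear interpolation keeps the operator
exactly linear and positivity-preserving; its bias is second order in
(dr/profile width) and sits well inside the 0.1% energy-conservation
tolerance for beam-resolved profiles. Totals are convolution invariant and
are always reported from the impulse run.

## Diffusion analytics

An analytic companion, never used inside the kernel: deep fluence decays as
exp(−μ_eff·z) with `μ_eff = √(3μ_a(μ_a+(1−g)μ_s))`; the 1% penetration
depth is `ln(100)/μ_eff`; layered attenuation multiplies per-layer factors
at normal incidence. For the reference flesh (μ_a = 0.024 cm⁻¹,
μ_s = 28.4 cm⁻¹, g = 0.61) this gives μ_eff = 0.8940 cm⁻¹ and a 1% depth of
5.151 cm. The commonly quoted figure of 5.08 cm for this tissue corresponds
to g ≈ 0.60; the package always computes from the supplied parameters
rather than adopting a quoted value, and the ~1.4% difference is attributed
to parameter rounding.

## Default parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `w_th` | 10⁻⁴ | roulette trigger threshold (weight) |
| `roulette_m` | 10 | survival factor; survival probability 1/m |
| `dr`, `dz` | 0.01 cm | radial / depth bin size |
| `nr` | 400 | radial bins (grid reaches 4 cm; beyond collapses into the last bin, flagged, and is excluded from per-area profiles) |
| `na` | 90 | exit-angle bins (1° over 0–90°) |
| `nz` | ceil(thickness/dz) | depth bins |
| beam | 0.5 J, 0.05 cm | Gaussian source energy and 1/e² radius |

The built-in peach preset (808 nm): air n=1.00 / skin n=1.337,
μ_a=0.075 cm⁻¹, μ_s=102 cm⁻¹, g=0.65, d=0.03 cm / flesh n=1.342,
μ_a=0.024 cm⁻¹, μ_s=28.4 cm⁻¹, g=0.61, d=2.34 cm / stone n=1.46. The sweep
helper `baseline_stack()` defaults to flesh 2.0 cm, the conventional
baseline for the optical-property grid, whose ±20% extremes are
μ_a ∈ {0.019, 0.029} and μ_s ∈ {22.7, 34.1} cm⁻¹.

Sweep grids are declared defaults, not canonical: d₂ ∈ {1.5, 2.0, 2.5,
3.0} cm for the stone comparison, d₁ ∈ {0.01, 0.03, 0.05} cm for skin,
d₂ ∈ {0.5, 1.0, 1.5, 2.0, 3.0} cm for flesh; all are arguments.

## Randomness and reproducibility

One seeded `numpy.random.Generator` drives an entire run, consumed inside
the compiled kernel in a fixed draw order; identical (seed, config, stack)
are bit-identical. Tracing is single-threaded. Scenario sweeps derive one
child seed per run from the master seed via `SeedSequence`, so sweep tables
are reproducible row-for-row.

## Problem sizes

The test suite runs its statistical checks at 1.5–2×10⁵ photons per
configuration, where 3·SE tolerances on the totals are a few parts per
thousand, and the stone-vs-no-stone ordering at 10⁶ photons because that
reflectance gap (~0.002) is the subtlest effect checked. The acceptance
script uses 3×10⁶ photons per condition, the conventional count for
published layered-fruit budgets. Every statistical assertion carries a
tolerance derived from the run's own Monte Carlo standard errors, so the
checks scale coherently with photon count.

## What the checks do and do not show

All quantitative checks run on the layered slab model with the fixed
single-wavelength parameters above. Passing them shows the transport
kernel, scoring, and convolution are correct *for that model*; it says
nothing about curved fruit surfaces, spatially varying optical properties,
wavelength dependence, stone remission, or detector coupling — none of
which are modeled. The pure-Python tracer exists as a readable structural
cross-check of the compiled kernel (same primitives, same draw order) and
is validated against closed-form oracles alongside it.

## Known limitations

* Planar geometry only; real drupes are curved on the centimeter scale of
  the penetration depth.
* The stone is lossless-opaque (absorbs whatever crosses); a reflective or
  remitting endocarp would raise deep reflectance.
* Single wavelength per run; spectra require one run per band.
* Unpolarized light; no fluorescence; steady state only.
* Exit-angle bins near 90° divide by small cos ᾱ and solid angles; their
  per-steradian densities are noisy at moderate photon counts.
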