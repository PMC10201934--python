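# Methods

This note records the physical model, the parameter choices that matter,
and what the package's synthetic runs do and do not establish about real
detectors.

## Event pipeline

Each simulated event is a 511 keV (or 1,000 keV) gamma travelling along +z
from a source 10 mm in front of a 3 × 3 × 20 mm³ crystal:

1. **Interaction depth** — exponential with the photoelectric attenuation
   coefficient (BGO at 511 keV: 0.056 cm²/g × 7.13 g/cm³ = 0.0399 /mm),
   resampled until it falls inside the crystal (only interacting gammas are
   kept).  Compton interactions are not modelled.
2. **Recoil electron** — a shell is selected (K shell, binding 0.091 MeV,
   probability 0.8; one L–M pseudo-shell at 0.008 MeV, probability 0.2);
   the electron carries E_γ − binding and leaves along a Sauter
   distribution f(θ) ∝ sin²θ/(1 − β cos θ)⁴ about the gamma axis.
3. **Stepwise transport** — described below.
4. **Cerenkov emission** per step, **optical ray tracing** to the
   photodetector, and the run-level analysis.

One seeded PCG64 generator drives a run; sweep points use sub-seeds spawned
from the master seed, so every output is reproducible bit-for-bit.

## Energy loss and range tables

Collision stopping power is the analytic Berger–Seltzer (ICRU-37) formula
with the material's Bragg-additivity mean excitation energy, computed with
the condensed-phase convention (elemental I × 1.13; oxygen bound in oxides
I = 106 eV), which gives I(BGO) = 534 eV — the published compound value.
The density-effect correction is omitted (sub-percent below 1 MeV).
Radiative loss uses the standard S_rad/S_col ≈ Z_eff·E/800 MeV rule of
thumb (≲ 8 % of the total here).  Tables are built once per material on a
200-point log grid from 1 keV to 2 MeV; the CSDA range is the cumulative
trapezoid of dE/(dE/dx).  Because the energy-loss model is analytic rather
than a cross-section database, absolute lengths carry a ~10–15 %
systematic: the computed CSDA range of a 0.420 MeV electron in BGO is
0.322 mm, about 8 % below the ~0.35 mm scale the full toolkit's tables
produce.  Delta-ray production is folded into continuous loss (no explicit
secondaries), and there is no range straggling — every track's total path
equals the CSDA range exactly.

## The stepping rule

Two limits bound each rectilinear step:

* **Cerenkov-threshold range cap.** While the electron is above the
  Cerenkov threshold (β > 1/max n, i.e. 53 keV in BGO), the step never
  exceeds range(KE) − range(KE_threshold): a single step cannot carry the
  emitting electron through the threshold.  Below threshold the electron
  takes its full remaining range in one step (the final-range rule for
  ranges far below a millimetre).  With no velocity limit this yields
  exactly two steps per track — one long step to the threshold, one short
  step (~13 μm) to rest — and a two-level mean step length of ~170 μm
  (the K/L–M mixture averages the 0.31 mm and 0.39 mm first steps).
* **Velocity-change limit.** When Δβ is set, the step shrinks to
  Δl = m·Δγ/(dE/dx) with Δγ evaluated for β_f = β(1 − Δβ).  Because β then
  decays geometrically until the threshold, the number of steps is
  ≈ ln(β₀/β_th)/Δβ, reproducing the measured scaling: mean steps of
  0.050 μm at Δβ = 0.01 %, 0.20 μm at 0.04 %, plateauing at the unlimited
  value for Δβ ≳ 30 % (where Δl exceeds the range cap).

Multiple scattering deflects the direction at each step end by a Gaussian
polar angle of Highland width θ₀ = 13.6 MeV/(βcp)·√(x/X₀)(1+0.038 ln x/X₀)
(X₀ = 11.2 mm for BGO), azimuth uniform.  The Highland model composes
correctly under step subdivision and needs no free parameter.  Tracking
stops at 1 keV, far below the 53 keV emission threshold.  Time advances
with the pre-step velocity; electron transit (~ps) is negligible against
photon transport.

## Cerenkov emission

The yield per mm is the trapezoid integral of the Frank–Tamm integrand on
the dispersion grid, clamped at zero below threshold; it is cached on a
velocity grid so per-step evaluation is one interpolation.  Per step the
photon count is Poisson; photons are placed uniformly along the step and
leave on the cone cos θ = 1/(β n(ε)), azimuth uniform, with ε sampled by
rejection under the max-n envelope (exact for tabulated dispersion).

Three conventions fix which β a step hands to the sampler:

* `local` (default) — β interpolated linearly to each photon's position;
  the expected count is the trapezoid average of the endpoint yields.
  This is subdivision-invariant (a step split in two emits the same
  expected count to < 0.5 %) and is the physically consistent choice for
  fine steps.  A photon landing below the local threshold is discarded.
* `mean-beta` — one β = (β_pre + β_post)/2 for the count and all photon
  properties, mimicking what production step-based toolkits do.  For a
  range-sized first step ending at the Cerenkov threshold this reproduces
  the coarse-step bias of the emitted count (≈ 13.5 vs ≈ 16.5 fitted mean
  at 511 keV) without changing fine-step results, where the two modes
  coincide.
* `pre` — pre-step β only, for sensitivity checks.

Scintillation (8,200 photons/MeV, isotropic, single 300 ns decay, 480 nm
Gaussian spectrum truncated to the window, no rise time or fast component)
is available but off by default; its effect on the Cerenkov analysis is a
uniform background and it is decimated (default 100×) when enabled.

## Materials

BGO: Bi₄Ge₃O₁₂, 7.13 g/cm³, stoichiometric mass fractions
(0.671/0.175/0.154).  The refractive index is interpolated linearly in
photon energy between the two published endpoints (2.36 at 320 nm, 2.07 at
800 nm) on a 21-point grid; only the endpoints are constrained by
publication, so the interior shape is a modelling choice.  The default
bulk absorption follows the universal BGO transmission-curve shape with
the intrinsic UV edge near 310–320 nm (3 mm at 320 nm → ~1.2 m at 800 nm);
a flat absorption length can be requested instead.  TlBr (7.56 g/cm³,
optical window 440–800 nm, index ≈ 2.5) uses a flat-ish configurable
curve, since its tables are not published; TlBr results are correspondingly
soft.  Materials round-trip through a YAML/JSON document for user-defined
radiators.

## Optical transport

The ray tracer advances each photon to the nearest face of the box, tests
exponential bulk absorption per segment, and resolves the surface:

* Every face is polished: unpolarised Fresnel against the outside medium
  (air behind the five wrapped faces, grease n = 1.5 at z = 0), evaluated
  on a micro-facet normal drawn with a Gaussian RMS tilt of 1.3° — the
  standard roughness characterisation of a polished crystal surface.  A
  geometrically perfect box would totally internally reflect most of the
  Cerenkov cone forever; the facet tilt is what lets trapped directions
  diffuse, as on real surfaces.
* Wrapped faces carry an effective per-interaction reflectivity of 0.98
  applied at all angles, total internal reflection included: measured
  wrapped-polished crystals lose a percent-level fraction per bounce even
  above the critical angle.  Photons that survive and transmit through the
  face re-enter diffusely from the Teflon (cosine-weighted).
* Photons transmitted through the detector face are detected (ideal
  photodetector, PDE = 1); transit time is path/(c/n_g) with the group
  index n_g = n + ε·dn/dε (phase-index speed available as a switch).
* A photon exceeding 1,000 reflections is recorded as trapped; every
  emitted photon ends in exactly one of {detected, absorbed, wrap-lost,
  trapped, escaped}, and the per-run audit enforces the balance.

## Known limitations

* Absolute step/range lengths inherit the ~10 % analytic stopping-power
  systematic; all Δβ *trends* are unaffected.
* The surface model is analytic, not a measured-reflectance look-up table.
  The detected-time *mean* is the single most sensitive output: the
  simulated mean Cerenkov transit is ≈ 0.48 ns for coarse stepping and
  ≈ 0.42 ns for fine stepping (medians ≈ 0.33/0.30 ns), with the fine-step
  run adding a prompt sub-0.1 ns backward population that is entirely
  absent with coarse steps.  Published full-toolkit distributions show the
  same ordering but a far smaller multi-bounce tail (means of ~0.3 ns and
  < 0.1 ns); matching those means would require an effective per-bounce
  cavity albedo near 0.9, which the available surface information does not
  pin down, so the defaults were left at their literature-scale values and
  the discrepancy is reported rather than fitted away.
* Electrons that cross the crystal boundary are not reflected or stopped;
  their out-of-crystal photons (≈ 0.5 %) are counted as escaped.
* No Compton recoils, positron transport, polarization, photodetector
  transit-time spread, or coincidence electronics.

## Problem sizes

Acceptance-style runs use 1,000 events per Δβ point (the study's event
count) and three representative Δβ values (unlimited, 0.04 %, and 0.02 %
at 1,000 keV) rather than the full 19-value sweep; the full grid is
available through `RunConfig.delta_beta`.  Unit and property tests use
25–400 events, which resolves every asserted effect at its stated
tolerance.
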