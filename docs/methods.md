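# Methods

## Physical model and assumptions

The package solves the forward problem of optoacoustics for a medium that is
*optically* layered but *acoustically* homogeneous. A laser pulse short
enough for stress confinement deposits a volumetric energy density
`W(r) = f(x, y) g(z)` (lateral beam profile times Beer–Lambert depth
profile); the induced pressure at a point detector is the optoacoustic
Poisson integral — the time derivative of the spherical-shell integral of
`W / |r_D − r'|` over the source volume. Assumptions baked in:

* no optical scattering (pure Beer–Lambert attenuation);
* plane-normal irradiation with an axially symmetric top-hat beam;
* homogeneous speed of sound, no acoustic attenuation or dispersion;
* ideal point detector, except for the foil-thickness temporal averaging.

Because sound speed is uniform, every axis is a propagation *distance*
`ct` in cm and the numerical core never needs a value of `c`. The overall
scale `f₀Γ/c` is folded into a single prefactor (default 4π, cancelling the
Green's-function denominator), so signals are in arbitrary units; a
least-squares scalar (`amplitude_calibration`) maps them onto measured
traces when needed.

## Fast solver numerics

The cylindrical solver works in a frame centred on the detector.

* **Quadrature nodes.** Midpoints in every coordinate:
  `ρ_i = (i+½)Δρ`, `z_k = (k+½)Δz`, `φ_j = jΔφ`. Midpoints avoid the
  degenerate ρ = 0 ring and represent each cell by its centre.
* **Azimuthal precomputation.** Ring weights
  `F_D(ρ_i) = ρ_i Σ_j f(x_D + ρ_i cosφ_j, ρ_i sinφ_j) Δφ` cost O(N_ρN_φ);
  on axis the closed form `2πρ f_I(ρ)` costs O(N_ρ). The rectangle rule on
  a smooth periodic integrand converges faster than any power of N_φ, so
  N_φ = 360 is far more than adequate.
* **Shell binning.** The δ-function is an indicator: each (ρ_i, z_k) cell
  adds `F_D g Δρ Δz / s` (s = distance to the detector) to the half-open
  distance bin containing s (ties go up). The bin origin is chosen so that
  on-axis slab distances fall at bin *centres*; with the natural choice
  (edges at the closest cell distance) every slab's mass is recorded half a
  bin too deep. Twenty-four guard bins of causal zeros pad both ends.
* **Bin width.** Default `max(Δρ, Δz)`: bins finer than the spatial
  quadrature only turn quantization into derivative noise.
* **Smoothing before differentiation.** The δ-to-indicator discretization
  leaves a staircase on the binned integrand; a 3-bin moving average is
  applied before the derivative. The width is kept below the foil window so
  it cannot alter any resolved feature; it is a config parameter
  (`smooth_bins`).
* **Derivative.** `np.gradient`: central differences inside, one-sided at
  the ends.
* **Foil averaging.** A foil of thickness Δw (μm) averages over a ct window
  of Δw·10⁻⁴ cm, rounded to the nearest odd bin count; moving averages
  shrink symmetrically at record edges rather than zero-padding, which
  would fabricate edge transients.

The default grid is (L_ρ, L_z) = (0.3, 0.15) cm with
(N_ρ, N_φ, N_z) = (6000, 360, 150), i.e. 0.5 μm radial and 10 μm axial
resolution; a solve takes well under a second. The Cartesian oracle
defaults to (300, 300, 75) voxels on a (0.6, 0.6, 0.15) cm box — enough
resolution to bound the fast solver's error (the two agree to < 4%
relative L∞ after normalization) without the hundreds of millions of
voxels a production-resolution oracle would need.

## Regime classification

`D = 2|z_D| / (μ a₀²)` with `a₀ = 1.25a` and μ the *thickness-weighted mean
over the absorbing layers only* (gaps and clear layers excluded). This
averaging domain is the one that makes the classifier consistent across
the bundled two-layer scenario (D = 0.15, 0.76, 15.2, 19.0 at
z_D = −0.04, −0.2, −4, −5 cm); averaging over the full computational depth
would not. D < 1 is near field (the on-axis signal traces `g(z)`), D > 1
far field (the signal is derivative-like: compression peaks at upward jumps
of μ_a, rarefaction dips at downward jumps).

## Far-field inversion

On the retarded depth axis `cτ = ct + z_D` (cτ = 0 at the absorber
surface), the far-field transient is approximately the temporal derivative
of the initial stress profile `p₀(z) ∝ g(z)`, so the cumulative trapezoidal
integral of the signal is the predictor `p₀,FF(z = cτ)`. Choices made where
the procedure is underdetermined:

* integration runs forward from the first sample with no sign flip (the
  leading compression makes the integral positive over the absorber);
* the reconstruction domain is clipped to cτ ∈ [0, L_z] before
  normalization — the exact profile is only defined there, and diffraction
  tails beyond it carry no depth information;
* both profiles are normalized to unit sample sum before comparison; the
  reconstruction is resampled onto the exact profile's grid by linear
  interpolation (both are smooth on the bin scale), with a one-grid-step
  tolerance at the domain edges because the two midpoint grids may be
  offset by up to half a bin.

The reconstruction error (MSE) falls monotonically with detector distance.
Its dominant term is the one-sided diffraction smear of the absorption
jumps, whose width scales like the transverse beam extent squared over the
propagation distance — so the achievable MSE ratio between two detector
distances is capped near the ratio of propagation distances to the jump,
e.g. ≈ (2.0 + 0.2)/(0.3 + 0.2) ≈ 4.4 between z_D = −0.3 and −2.0 cm for
the PIII phantom (measured ≈ 3.5). The foil window only becomes the
limiting factor at standoffs of several centimetres more.

## Bundled scenarios

The presets are the package's validation fixtures; every parameter is
generated in code, no data files exist.

| name | layers (μ_a in cm⁻¹) | beam | detector |
|---|---|---|---|
| fig3a | 10 over 0–0.05 cm, 20 over 0.05–0.10 cm | a = 0.15, d = a/4 | z_D = −0.04 / −4.0 |
| fig3b | fig3a with layer order reversed | same | same |
| fig4 | fig3a stack | same | z_D ∈ {−0.2, −1, −5} × x_D ∈ {0, 0.1, 0.2} |
| PI | 11 over 0.3–0.395 cm (detector frame) | a = 0.054, R = 1.5 | z_D = −0.3 |
| PII | 1.4 over 0.3–0.408, 11 over 0.408–0.504 | a = 0.056, R = 1.2 | z_D = −0.3 |
| PIII | 1.4 over 0.3–0.5, 11 over 0.5–0.595 | a = 0.08, R = 1.2 | z_D = −0.3 |

The phantom presets store their layer coordinates in the detector-relative
frame in which they are quoted (the surface-relative solver stack is
derived by subtracting the standoff |z_D| = 0.3 cm), keeping the nominal
numbers verbatim in the JSON config. `d` is derived as `R·a`; for PI that
makes the Gaussian edge wider than the flat top — unusual, but taken at
face value. The foil default is the deliberately oversized Δw = 50 μm; a
real PVDF foil is ~10 μm and both are plain config values. All scenarios
are deterministic: the package contains no randomness anywhere.

What the synthetic scenarios do *not* emulate: off-normal irradiation and
surface refraction, beam asymmetry, the finite (1 mm) active detector
area, transducer/amplifier impulse response, acoustic attenuation, and
sound-speed heterogeneity. Passing tests therefore validate the numerics
of the stated model, not agreement with any particular measured voltage
trace.

## Numerical edge cases

* Layers own half-open depth intervals `[z_start, z_end)`, so μ_a is
  single-valued at internal boundaries; gaps are allowed, overlaps are
  validation errors.
* A fully clear stack yields an identically zero signal (the Cartesian
  solver warns); normalizing a zero-sum profile is an error rather than a
  silent NaN.
* Feature extraction uses a prominence threshold relative to max|p|
  (default 5%): above the binning-noise floor, below the smallest feature
  of the bundled scenarios. Shallow physical shoulder dips between main
  features do get reported.
* The near-field "signal traces g(z)" check correlates the transient with
  `g` over the absorber support *trimmed by half a foil window at each
  edge*: a finite foil cannot reproduce the boundary discontinuities, and
  the trim matches the one-foil-window localization tolerance used for the
  far-field features.

## Known limitations

* Peak amplitudes in the far field approach the 1/|z_D| spherical-spreading
  law only once the (distance-independent) foil window dominates the
  (1/|z_D|-shrinking) diffraction smear of the layer jumps; the integrated
  |p| obeys the law much earlier.
* The oracle solver is O(N_xN_yN_z) and unoptimized by design.
* No tomographic (multi-detector) reconstruction, time reversal, or
  attenuation correction.
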