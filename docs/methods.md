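# Methods

## Model

`fluocascade` solves steady-state light transport in laterally infinite
layered slabs by analog Monte Carlo. The radiance obeys the radiative
transfer equation extended with a fluorescence source term: besides
elastic scattering (phase function p) and absorption, an absorbed photon may
reappear isotropically at a longer (or shorter) wavelength drawn from the
fluorophore's intrinsic emission density P̃f(λ). Core assumptions:

- **Excitation independence.** Φf and P̃f(λ) do not depend on the absorbed
  photon's wavelength (emission always proceeds from the relaxed excited
  state). One consequence is that anti-Stokes emission is permitted: a
  re-emitted wavelength may be shorter than the absorbed one, in which case
  the Stokes weight factor λ'/λ exceeds one.
- **Additive mixtures.** A layer's coefficients are concentration-weighted
  sums of its components' reference spectra (Beer–Lambert linearity);
  each component keeps its own μa(λ), μs(λ), g(λ), and fluorescence
  attributes. The absorbing (or scattering) component at an interaction is
  selected by its share of the total coefficient.
- **Analog transport.** Free paths are exponential in μt = μa + μs;
  absorption vs. scattering is decided with probability μa/μt; survival at
  a fluorophore is a Bernoulli draw against Φf. No implicit capture and no
  Russian roulette: the photon weight carries only the accumulated Stokes
  factor, which telescopes so that an escaping photon's weight is exactly
  λ_launch/λ_exit (the kernel computes it in that closed form).
- **Specular boundaries.** Unpolarized Fresnel reflection/refraction at
  z-normal interfaces; total internal reflection reflects with certainty.
  No surface roughness.
- **Geometry.** Slab layers are laterally infinite; exits through the top
  are reflectance, through the bottom transmission. z = 0 at the
  illuminated surface.

Units: nm for wavelengths, mm for lengths, mm⁻¹ for coefficients.
Wavelength-resolved quantities live on a half-open bin grid, by default
1 nm bins over 350–800 nm; tabulated properties are linearly interpolated
onto bin centers and never extrapolated (out-of-range input is an error).

## Randomness and determinism

Each photon owns a counter-based splitmix64 substream derived from
(seed, photon index), so results are bit-reproducible for a given seed and
photon count and independent of execution order. Emission wavelengths are
drawn by inverse transform from a cached 4097-point quantile table of the
truncated mixture CDF (interpolation error far below sampling noise at 10⁶
draws); source wavelengths by inverse transform of the binwise source CDF,
uniform within a bin.

## Emission distribution

P̃f(λ) is a three-component Gaussian mixture with w₃ = 1 − w₁ − w₂ (eight
free parameters), truncated to the grid range and renormalized — the
idealized normalization over (0, ∞) is not implementable on a finite grid.
Components are kept sorted by mean so fits are comparable under label
switching. Initialization from a measured spectrum is a bounded nonlinear
least-squares fit to the area-normalized spectrum with three starts
(moment-based and jittered) to avoid local minima.

**Identifiability.** The mixture means are individually identifiable from
band shapes only when components are separated by roughly 2.5× the narrower
neighbour's width. For strongly overlapping mixtures (the default dye-like
fixture has separations ≈ 1.5σ), the broad tail component's mean trades off
against its width along a shallow curved valley; any estimator then shows a
noise-level-dependent displacement of that mean (several nm at 10⁶ photons
per evaluation). The recovery fixture used for validation
(`fixtures.make_recovery_emission`) satisfies the separation condition; the
limitation for overlapping mixtures is intrinsic to the inference problem,
not to the optimizer.

## Integrating-sphere twin

Sample-exit photons enter a 150 mm sphere through the sample port at the
south pole. Each record's straight-line continuation lands on the sphere
and is classified against the detector field-of-view patch (→ Φ_D0),
spherical-cap surfaces (ports at ρ = 0, fold mirror, the sample itself), or
the wall. The detected flux is the direct term plus the geometric series
over diffuse wall bounces (open ports ρ = 0); the sample surface's
ρ_sample(λ) comes from an auxiliary run with cosine-distributed incidence —
run with the fluorescence branch disabled, so it is the elastic
same-wavelength reflectance and independent of the fitted parameters, which
lets the inversion precompute it once. Detected spectra are normalized to
the incident radiant power (source power per launched photon), making them
independent of the photon budget up to Monte Carlo noise.

Two estimators exist for the irradiation split. The default assigns each
photon's weight to exactly one destination (binary classification). The
twin's detection chain instead uses an azimuthally averaged split: the
layered-slab problem is statistically invariant under rotation about the
beam axis, so replacing each cap-hit indicator with its exact
azimuth-averaged probability (a closed-form band-overlap fraction) is a
conditional expectation — identical means, far lower variance. This matters
because direct-FOV photons carry ~80× the detection efficiency of diffuse
photons, so the binary estimator's detected flux is dominated by a small
photon subpopulation. Conservation (assigned weight = exit weight) is exact
in both modes. Idealizations: exit positions beyond the port aperture are
clamped to the port rim (the slab is laterally infinite, the port is not),
and port/mirror/FOV geometry are fixture values living in config — the
caps must be mutually disjoint.

Instrument broadening is a discrete convolution with a measured (here:
Gaussian, σ = 3.7 nm fixture) kernel; deconvolution is Richardson–Lucy with
a 50-iteration cap and early stop at relative change < 10⁻⁶.

## Yield estimators and the classical correction

On a completed run, three photon-count estimators are reported:
**intrinsic** (re-emission events / absorption events in fluorescent
components — the defining ratio, converging to the configured Φf),
**uncorrected** (escaped photons with ≥ 1 conversion cycle / primary
absorption events in fluorescent components; "primary" means the photon had
not yet undergone any conversion), and **gross** (same numerator / primary
absorptions in any component). With non-negative spectral overlap,
gross ≤ uncorrected ≤ intrinsic.

The classical correction Φf = Φf,obs/(1 − a + a·Φf,obs) needs a
re-absorption probability `a`. Two overlap integrals are provided: a
fixed-effective-path form, a = ∫ P̃f(λ)(1 − e^{−μa(λ)ℓ}) dλ (ℓ
configurable, default half the slab thickness), and a geometry-aware form
that averages the Beer–Lambert escape factor over a uniform emission depth
and an isotropic direction in a slab of thickness d, which reduces to
escape(τ) = (1/τ)(1/2 − E₃(τ)) with τ = μa·d. The straight-line escape
assumption makes the latter exact for non-scattering media, where it
recovers the configured Φf from the simulated uncorrected yield to better
than 0.01; the fixed-path form with ℓ = d/2 underestimates re-absorption
there by design simplicity. In scattering media both are approximations and
the cascade simulation itself is the reference.

## Inversion

Nine parameters are fitted: Φf and the eight mixture parameters, matching
twin-simulated reflectance and transmission spectra to measured ones.
Transforms keep iterates physical: logit(Φf), log(σᵢ), and an interior
simplex map (two log-ratios) for the weights. Every objective evaluation
reuses one seed (common random numbers), so the objective is a deterministic
function of the parameters.

Because transport is analog, that deterministic objective is a fine
staircase: an infinitesimal parameter change flips individual photon
histories. Finite-difference derivatives therefore use fixed absolute steps
on the transformed scale — 0.12 in logit(Φf) (≈ 0.02 in Φf), 0.5 nm in the
means, 2% in the widths, 0.05 in the weight log-ratios — large enough to
average over many flipped histories, small against parameter curvature.
Levenberg–Marquardt runs with Jacobian-norm scaling. The residual is the
concatenated R and T vectors (RMSE objective); optional
`weighting="inverse-variance"` divides residuals by a shot-noise proxy
(√ of a smoothed copy of the measurement — smoothed so the weights are
exogenous to the per-bin noise). Unweighted is the default; the weighted
estimator is markedly more efficient for spectra whose bin values span
orders of magnitude.

**Uncertainties.** Statistical errors are square roots of the diagonal of a
heteroscedasticity-and-correlation-consistent sandwich covariance: the local
residual variance is estimated by a 31-bin moving average of squared
residuals (scaled by an effective-degrees-of-freedom factor m/(m − p·l_eff),
where l_eff is the instrument-kernel correlation length), combined with the
kernel's autocorrelation, and propagated through (JᵀJ)⁻¹ Jᵀ Σ J (JᵀJ)⁻¹ and
the delta method to the natural scale. 95% intervals are ±1.96 stat_error.
A plain iid-residual covariance is badly miscalibrated here because Monte
Carlo shot noise and multiplicative detector noise differ by orders of
magnitude across the spectrum and the instrument kernel correlates
neighbouring bins. Calibration was verified against replicate-fit scatter
(eval-seed scatter 0.0021 vs. reported 0.0018 at the validation sizes).

## Synthetic fixtures and what they do (not) show

The generator emulates a Rhodamine-6G-like study system with parametric
spectra: a Gaussian absorption band (peak 520 nm, σ 25 nm, peak 0.5 mm⁻¹ at
reference concentration) overlapping the blue edge of a three-Gaussian
emission (means 545/570/610 nm, σ 12/18/30 nm, weights 0.50/0.35/0.15),
Φf = 0.90; a non-absorbing forward scatterer (reduced scattering 12 mm⁻¹ at
520 nm, g = 0.9, λ⁻¹ slope); a 1 mm BK7 / 4 mm medium / 1 mm BK7 cuvette in
air (glass n = 1.5168 with a small realistic absorption 10⁻⁴ mm⁻¹; ethanol
n = 1.36, PDMS n = 1.41); a Gaussian excitation band at 490 nm (15 nm FWHM);
and 1% multiplicative detector noise on synthetic measurements.
Concentration series are linear weight scalings (1:2:4). An index-matched
cuvette variant (all indices equal) removes Fresnel interfaces for analytic
tests; the index-mismatched non-scattering case would trap isotropically
emitted fluorescence in total-internal-reflection light-guide modes that
analog transport can only terminate through the small glass absorption, so
quantitative validation uses either index-matched or scattering variants.

Passing tests on these fixtures demonstrate the transport, detection and
inference machinery under known truth. They do not demonstrate quantitative
agreement with any real dye: real absorption/emission spectra are not
two-or-three-Gaussian, real sphere coatings and port geometries differ from
the fixture values, and measured optical properties carry systematic errors
that the synthetic pipeline does not model.

## Problem sizes

Validation runs use 10⁵–10⁶ photons per forward simulation. The
parameter-recovery experiment uses 10⁶-photon synthetic measurements with 1%
noise, 2.5×10⁵ photons per objective evaluation, ten replicate fits from a
perturbed start (+3/−2/+4 nm in the means, ×1.2 in the widths, Φf from
0.75), with the weighted objective and the azimuth-averaged twin. At these
sizes the recovered Φf lies within ±0.007 of truth (replicate scatter
σ ≈ 0.003) and all mixture means within 0.5 nm for the resolvable mixture.

## Known limitations

- Layered slabs only; no lateral heterogeneity, no time resolution, no
  polarization.
- Analog transport makes deep-overlap, high-albedo cascades expensive; there
  is no variance-reduction weighting inside the transport itself.
- The classical-correction module's overlap integrals assume straight-line
  escape; in scattering media they are heuristic.
- Emission-parameter identifiability degrades for strongly overlapping
  mixture components (see above); reported uncertainties remain calibrated,
  but the broad-component mean can carry multi-nm uncertainty.
- The sphere twin is an analytic cap model, not a full radiometric ray
  trace; baffles and non-cap port shapes are out of scope.
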