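"""Deterministic synthetic fixtures: dye-like fluorophore, microsphere
scatterer, glass cuvette stacks, sources, sphere geometries and noisy
synthetic measurements.

The fixtures emulate a Rhodamine-6G-like system: a single absorption band
overlapping the blue edge of a three-Gaussian emission distribution with a
quantum yield near 0.9, a forward-scattering microsphere suspension, and a
glass/medium/glass cuvette (1 mm BK7 / 4 mm medium / 1 mm BK7) in air.  All
spectra are parametric (no digitized literature curves); everything is
bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emission import EmissionGMM
from .spectral import (
    ComponentOpticalProperties,
    Layer,
    LayeredSample,
    SpectralGrid,
    Spectrum,
)
from .sphere import InstrumentFunction, SphereGeometry, SphereSurface, simulate_detected_spectra

__all__ = [
    "FixtureSpec",
    "make_fluorophore",
    "make_scatterer",
    "make_glass",
    "make_cuvette",
    "make_source",
    "make_emission_truth",
    "make_recovery_emission",
    "make_sphere_geometry",
    "make_solution_sample",
    "make_synthetic_measurement",
    "PRESETS",
]

N_BK7 = 1.5168
N_ETHANOL = 1.36
N_PDMS = 1.41


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system (defaults = study conditions)."""

    seed: int = 0
    # fluorophore absorption band
    absorption_peak_nm: float = 520.0
    absorption_sigma_nm: float = 25.0
    absorption_peak_mu_a: float = 0.5  # per mm at reference concentration
    phi_f: float = 0.90
    # intrinsic emission (3-component GMM truth)
    emission_means_nm: tuple = (545.0, 570.0, 610.0)
    emission_sigmas_nm: tuple = (12.0, 18.0, 30.0)
    emission_weights: tuple = (0.50, 0.35, 0.15)
    # scatterer
    mus_prime_target: float = 12.0  # per mm at lambda_ref
    scatter_g: float = 0.90
    scatter_slope: float = 1.0  # mu_s ~ (lambda/lambda_ref)^-slope
    lambda_ref_nm: float = 520.0
    # source
    source_center_nm: float = 490.0
    source_fwhm_nm: float = 15.0
    source_power: float = 1.0
    # measurement noise
    noise_relative: float = 0.01


def _gaussian_band(grid: SpectralGrid, peak_nm, sigma_nm, amplitude, floor=1e-12):
    lam = grid.centers
    band = amplitude * np.exp(-0.5 * ((lam - peak_nm) / sigma_nm) ** 2)
    band[band < floor] = 0.0  # exact zeros far from the band
    return band


def make_emission_truth(spec: FixtureSpec, grid: SpectralGrid) -> EmissionGMM:
    return EmissionGMM(
        np.asarray(spec.emission_means_nm, float),
        np.asarray(spec.emission_sigmas_nm, float),
        np.asarray(spec.emission_weights, float),
        support=(grid.lo, grid.hi),
    )


def make_recovery_emission(grid: SpectralGrid) -> EmissionGMM:
    """Emission truth for parameter-recovery experiments.

    Component separation exceeds 2.5x the narrower neighbour's width, the
    regime in which all three mixture means are individually identifiable
    from band shapes.  The default R6G-like mixture (separations ~1.5 sigma)
    is deliberately harder: its broad tail component trades its mean against
    its width, and recovery there is limited by that degeneracy rather than
    by the pipeline (see the methods note).
    """
    return EmissionGMM(
        np.array([545.0, 590.0, 650.0]),
        np.array([12.0, 15.0, 20.0]),
        np.array([0.50, 0.35, 0.15]),
        support=(grid.lo, grid.hi),
    )


def make_fluorophore(
    spec: FixtureSpec,
    grid: SpectralGrid,
    name: str = "dye",
    zero_overlap: bool = False,
) -> ComponentOpticalProperties:
    """Dye component: Gaussian absorption band, negligible scattering.

    The default band overlaps the blue edge of the emission distribution; the
    ``zero_overlap`` variant moves the absorption band strictly below the
    emission support (no re-absorption possible).
    """
    if zero_overlap:
        peak, sigma = 420.0, 12.0
    else:
        peak, sigma = spec.absorption_peak_nm, spec.absorption_sigma_nm
    mu_a = _gaussian_band(grid, peak, sigma, spec.absorption_peak_mu_a)
    if zero_overlap:
        mu_a[grid.centers >= 480.0] = 0.0
    emission = make_emission_truth(spec, grid)
    if zero_overlap:
        lo = 500.0
        emission = EmissionGMM(
            emission.means, emission.sigmas, emission.weights, support=(lo, grid.hi)
        )
    return ComponentOpticalProperties(
        name=name,
        grid=grid,
        mu_a=mu_a,
        mu_s=np.zeros(grid.n_bins),
        g=np.zeros(grid.n_bins),
        is_fluorescent=True,
        phi_f=spec.phi_f,
        emission=emission,
    )


def make_scatterer(
    spec: FixtureSpec, grid: SpectralGrid, name: str = "microspheres"
) -> ComponentOpticalProperties:
    """Non-absorbing forward scatterer hitting the reduced-scattering target.

    mu_s(lambda) = mu_s(lambda_ref) (lambda/lambda_ref)^-slope with
    mu_s(lambda_ref) = mus_prime_target / (1 - g).
    """
    if not -1.0 < spec.scatter_g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    mus_ref = spec.mus_prime_target / (1.0 - spec.scatter_g)
    lam = grid.centers
    mu_s = mus_ref * (lam / spec.lambda_ref_nm) ** (-spec.scatter_slope)
    return ComponentOpticalProperties(
        name=name,
        grid=grid,
        mu_a=np.zeros(grid.n_bins),
        mu_s=mu_s,
        g=np.full(grid.n_bins, spec.scatter_g),
    )


def make_glass(grid: SpectralGrid, name: str = "bk7") -> ComponentOpticalProperties:
    """BK7-like glass: non-scattering, very weakly absorbing."""
    return ComponentOpticalProperties(
        name=name,
        grid=grid,
        mu_a=np.full(grid.n_bins, 1e-4),
        mu_s=np.zeros(grid.n_bins),
        g=np.zeros(grid.n_bins),
    )


def make_cuvette(
    medium_components,
    grid: SpectralGrid,
    medium_index: float = N_ETHANOL,
    index_matched: bool = False,
    glass: ComponentOpticalProperties | None = None,
) -> LayeredSample:
    """Glass(1 mm)/medium(4 mm)/glass(1 mm) stack in air.

    ``index_matched=True`` sets every index (including the surroundings) to
    the medium index, the analytic-test variant with no Fresnel interfaces.
    """
    if glass is None:
        glass = make_glass(grid)
    n_glass = medium_index if index_matched else N_BK7
    n_out = medium_index if index_matched else 1.0
    layers = [
        Layer(1.0, n_glass, [(glass, 1.0)]),
        Layer(4.0, medium_index, list(medium_components)),
        Layer(1.0, n_glass, [(glass, 1.0)]),
    ]
    return LayeredSample(grid=grid, layers=layers, n_above=n_out, n_below=n_out)


def make_bare_slab(
    components,
    grid: SpectralGrid,
    thickness_mm: float = 4.0,
    index: float = N_ETHANOL,
    index_matched: bool = True,
) -> LayeredSample:
    """Single-layer slab; index-matched by default for analytic tests."""
    n_out = index if index_matched else 1.0
    return LayeredSample(
        grid=grid,
        layers=[Layer(thickness_mm, index, list(components))],
        n_above=n_out,
        n_below=n_out,
    )


def make_source(spec: FixtureSpec, grid: SpectralGrid) -> Spectrum:
    sigma = spec.source_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = _gaussian_band(grid, spec.source_center_nm, sigma, 1.0)
    if values.sum() <= 0:
        raise ValueError("source band outside the grid")
    return Spectrum(grid, spec.source_power * values / values.sum())


def make_sphere_geometry(with_mirror: bool = False) -> SphereGeometry:
    """150 mm sphere with four ports (fixture port sizes; config in practice).

    Ports: sample (entry, sample-linked reflectance), reflection and
    normalization (open), detector coupling (open).  The reflectance-side
    geometry adds the fold mirror.
    """
    surfaces = [
        SphereSurface("sample", 314.16, None, np.array([0.0, 0.0, -1.0]), kind="sample"),
        SphereSurface("reflection_port", 314.16, 0.0, np.array([0.0, 0.0, 1.0]), kind="port"),
        SphereSurface("normalization_port", 176.7, 0.0, np.array([1.0, 0.0, 0.0]), kind="port"),
        SphereSurface("detector_port", 78.5, 0.0, np.array([-1.0, 0.0, 0.0]), kind="port"),
    ]
    if with_mirror:
        surfaces.append(
            SphereSurface("mirror", 100.0, 0.95, np.array([0.0, -0.6, 0.8]), kind="mirror")
        )
    return SphereGeometry(
        diameter_mm=150.0,
        wall_reflectance=0.95,
        detector_area_mm2=78.5,
        fov_area_mm2=700.0,
        fov_direction=np.array([0.0, 0.5, 0.866]),
        surfaces=surfaces,
    )


def make_solution_sample(
    spec: FixtureSpec,
    grid: SpectralGrid,
    concentration_weight: float = 1.0,
    scatterer_weight: float = 1.0,
    medium_index: float = N_ETHANOL,
    index_matched: bool = False,
) -> tuple[LayeredSample, ComponentOpticalProperties]:
    """Cuvette filled with dye + scatterer; returns (sample, dye component)."""
    dye = make_fluorophore(spec, grid)
    comps = [(dye, concentration_weight)]
    if scatterer_weight > 0:
        comps.append((make_scatterer(spec, grid), scatterer_weight))
    sample = make_cuvette(
        comps, grid, medium_index=medium_index, index_matched=index_matched
    )
    return sample, dye


def make_synthetic_measurement(
    sample: LayeredSample,
    source: Spectrum,
    geometry_r: SphereGeometry,
    geometry_t: SphereGeometry,
    n_photons: int,
    seed: int,
    noise_relative: float = 0.01,
    irf: InstrumentFunction | None = None,
    rho_sample: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum, dict]:
    """Twin-generated (R, T) measurement with multiplicative Gaussian noise.

    Returns the noisy pair plus a truth record (the dye's quantum yield and
    emission parameters, the seeds and photon counts) for test harnesses.
    """
    r_det, t_det = simulate_detected_spectra(
        sample,
        source,
        geometry_r,
        geometry_t,
        n_photons,
        seed,
        irf=irf,
        rho_sample=rho_sample,
    )
    rng = np.random.default_rng(seed + 1)
    r_vals = r_det.values.copy()
    t_vals = t_det.values.copy()
    if noise_relative > 0:
        r_vals = r_vals * (1.0 + noise_relative * rng.standard_normal(r_vals.size))
        t_vals = t_vals * (1.0 + noise_relative * rng.standard_normal(t_vals.size))
        r_vals = np.maximum(r_vals, 0.0)
        t_vals = np.maximum(t_vals, 0.0)
    dye = next(
        c for layer in sample.layers for c, _ in layer.components if c.is_fluorescent
    )
    truth = {
        "phi_f": dye.phi_f,
        "emission": dye.emission.to_dict(),
        "n_photons": int(n_photons),
        "seed": int(seed),
        "noise_relative": float(noise_relative),
    }
    return Spectrum(sample.grid, r_vals), Spectrum(sample.grid, t_vals), truth


PRESETS = {
    "ethanol-c1": dict(concentration_weight=1.0, medium_index=N_ETHANOL),
    "ethanol-c3": dict(concentration_weight=4.0, medium_index=N_ETHANOL),
    "pdms-a": dict(concentration_weight=1.2, medium_index=N_PDMS),
    "zero-overlap": dict(concentration_weight=1.0, medium_index=N_ETHANOL),
}
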