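"""Digital twin of the integrating-sphere detection system.

The sphere is modelled analytically: light leaving the sample enters the
sphere through the sample port, lands either in the detector field of view
(direct contribution), on a named surface patch (ports, mirror, the sample
itself), or on the barium-sulfate wall, and the detected flux follows the
geometric series over diffuse wall bounces

    Phi_D = Phi_D0 + (A_det / A_sph) * sum_n rho_n Phi_n / (1 - sum_l rho_l A_l / A_sph).

Open ports carry rho = 0.  The same model inverted yields the true source
spectrum from a detector reading (transmission and mirror-folded reflectance
configurations).  The spectrometer's finite resolution is applied as a
discrete convolution with a measured instrument function and removed by
iterative non-negative deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import LayeredSample, SpectralGrid, Spectrum
from .transport import TallySet, run_forward

__all__ = [
    "SphereSurface",
    "SphereGeometry",
    "InstrumentFunction",
    "irradiation_split",
    "detected_flux",
    "sample_diffuse_reflectance",
    "invert_source_transmission",
    "invert_source_reflectance",
    "convolve_instrument",
    "deconvolve_instrument",
    "simulate_detected_spectra",
]


@dataclass
class SphereSurface:
    """A spherical-cap patch of the sphere interior.

    ``reflectance`` may be a scalar, a per-bin array, or None for a
    sample-linked surface whose rho(lambda) is supplied at evaluation time
    (computed by the auxiliary cosine-source reflectance run).  ``direction``
    is the unit vector from the sphere center to the cap center.
    """

    label: str
    area_mm2: float
    reflectance: float | np.ndarray | None
    direction: np.ndarray
    kind: str = "port"  # 'port' (open), 'mirror', 'sample', 'patch'

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)
        if self.area_mm2 <= 0:
            raise ValueError(f"surface {self.label!r}: area must be > 0")

    def rho_on(self, grid: SpectralGrid, sample_rho: np.ndarray | None) -> np.ndarray:
        if self.reflectance is None:
            if sample_rho is None:
                raise ValueError(
                    f"surface {self.label!r} is sample-linked but no sample "
                    "reflectance was provided"
                )
            return np.asarray(sample_rho, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape == ():
            r = np.full(grid.n_bins, float(r))
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError(f"surface {self.label!r}: reflectance outside [0, 1]")
        return r


@dataclass
class SphereGeometry:
    """Sphere dimensions, wall coating, ports and detector field of view.

    The entry (sample) port sits at the south pole; light from the sample
    travels into the sphere with a positive z direction component.  The wall
    area is the sphere area minus all configured surface patches; the
    detector FOV patch is a wall region whose direct hits are recorded as
    Phi_D0 and bypass the diffuse-mixing series.
    """

    diameter_mm: float = 150.0
    wall_reflectance: float | np.ndarray = 0.95
    detector_area_mm2: float = 78.5
    fov_area_mm2: float = 700.0
    fov_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.5, 0.866]))
    surfaces: list[SphereSurface] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.fov_direction, dtype=float)
        self.fov_direction = d / np.linalg.norm(d)
        if self.total_patch_area + self.fov_area_mm2 >= self.sphere_area_mm2:
            raise ValueError("surface patches exceed the sphere area")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def sphere_area_mm2(self) -> float:
        return np.pi * self.diameter_mm**2

    @property
    def total_patch_area(self) -> float:
        return float(sum(s.area_mm2 for s in self.surfaces))

    @property
    def wall_area_mm2(self) -> float:
        # Open/used ports do not count as wall; the FOV patch is wall.
        return self.sphere_area_mm2 - self.total_patch_area

    def wall_rho_on(self, grid: SpectralGrid) -> np.ndarray:
        r = np.asarray(self.wall_reflectance, dtype=float)
        if r.shape == ():
            r = np.full(grid.n_bins, float(r))
        return r

    def cap_cos_half_angle(self, area_mm2: float) -> float:
        """cos(alpha) of a spherical cap of the given area."""
        c = 1.0 - area_mm2 / (2.0 * np.pi * self.radius_mm**2)
        if not -1.0 <= c <= 1.0:
            raise ValueError("cap area exceeds the sphere")
        return c

    def find(self, label: str) -> SphereSurface:
        for s in self.surfaces:
            if s.label == label:
                return s
        raise KeyError(f"no surface labelled {label!r}")


@dataclass
class InstrumentFunction:
    """Normalized spectrometer line-spread kernel on the grid spacing."""

    kernel: np.ndarray  # odd length, centered, sums to 1

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size % 2 == 0:
            raise ValueError("kernel must be 1-D with odd length")
        if np.any(k < 0):
            raise ValueError("kernel must be non-negative")
        s = k.sum()
        if s <= 0:
            raise ValueError("kernel must have positive mass")
        self.kernel = k / s

    @classmethod
    def gaussian(cls, sigma_nm: float, step_nm: float = 1.0, half_width: float = 4.0):
        n = max(int(np.ceil(half_width * sigma_nm / step_nm)), 1)
        x = np.arange(-n, n + 1) * step_nm
        return cls(np.exp(-0.5 * (x / sigma_nm) ** 2))

    @classmethod
    def delta(cls):
        return cls(np.array([1.0]))


# ---------------------------------------------------------------------------
# irradiation split
# ---------------------------------------------------------------------------


def _entry_points(records: np.ndarray, geometry: SphereGeometry, port_radius_mm: float):
    """Map slab-exit positions to points on the sphere near the south pole.

    Exit positions beyond the port aperture are clamped to the rim (the slab
    is laterally infinite, the port is not; see methods note).
    """
    R = geometry.radius_mm
    x = records["x"].astype(float).copy()
    y = records["y"].astype(float).copy()
    r = np.hypot(x, y)
    over = r > 0.99 * port_radius_mm
    if np.any(over):
        scale = 0.99 * port_radius_mm / np.maximum(r[over], 1e-300)
        x[over] *= scale
        y[over] *= scale
    z = -np.sqrt(np.maximum(R**2 - x**2 - y**2, 0.0))
    return np.column_stack([x, y, z])


def _cap_band_fraction(theta_q, theta_s, cos_alpha):
    """Azimuth-averaged probability that a landing point at polar angle
    theta_q falls inside a cap centered at polar angle theta_s.

    The slab problem is azimuthally symmetric, so averaging the hit
    indicator over the azimuth is an exact conditional expectation; the
    fraction is the angular overlap of the landing circle with the cap.
    """
    cos_q, sin_q = np.cos(theta_q), np.sin(theta_q)
    cos_s, sin_s = np.cos(theta_s), np.sin(theta_s)
    denom = sin_q * sin_s
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (cos_alpha - cos_q * cos_s) / denom
    frac = np.where(x >= 1.0, 0.0, np.where(x <= -1.0, 1.0, np.arccos(np.clip(x, -1, 1)) / np.pi))
    # degenerate: cap at a pole or landing circle collapsed to a point
    polar = denom < 1e-12
    inside = (cos_q * cos_s + denom) >= cos_alpha  # angular distance <= alpha
    return np.where(polar, inside.astype(float), frac)


def irradiation_split(
    records: np.ndarray,
    geometry: SphereGeometry,
    grid: SpectralGrid,
    sample_port_label: str = "sample",
    azimuthal_average: bool = False,
) -> tuple[Spectrum, dict[str, Spectrum]]:
    """Assign each sample-exit photon's weight to the detector FOV, a surface, or the wall.

    Records are slab-exit records already transformed so that a positive z
    direction component points into the sphere.  Each photon's straight-line
    continuation is intersected with the sphere; the landing point is
    classified against the FOV cap and every configured surface cap, in that
    order; anything else is wall.  Photons with a non-positive z component
    head back into the sample and are assigned to the sample-port surface.
    The assigned weight equals the total exit weight exactly.

    With ``azimuthal_average=True`` each record's weight is split across the
    caps by the exact azimuth-averaged hit probability instead of a binary
    classification (valid because the layered-slab problem is statistically
    invariant under rotation about the beam axis).  Expectations are
    unchanged; the variance of the direct-FOV channel, which is otherwise
    carried by very few photons, drops dramatically.  Conservation is exact
    in both modes.
    """
    nbins = grid.n_bins
    phi_d0 = np.zeros(nbins)
    phi_n = {s.label: np.zeros(nbins) for s in geometry.surfaces}
    wall = np.zeros(nbins)

    if records.size == 0:
        out = {label: Spectrum(grid, v) for label, v in phi_n.items()}
        out["wall"] = Spectrum(grid, wall)
        return Spectrum(grid, phi_d0), out

    try:
        port_radius = np.sqrt(geometry.find(sample_port_label).area_mm2 / np.pi)
    except KeyError:
        port_radius = 0.1 * geometry.radius_mm

    p0 = _entry_points(records, geometry, port_radius)
    u = np.column_stack(
        [records["ux"].astype(float), records["uy"].astype(float), records["uz"].astype(float)]
    )
    w = records["weight"].astype(float)
    bins = grid.index_of(np.clip(records["lam"], grid.lo, np.nextafter(grid.hi, 0)))

    into = u[:, 2] > 1e-12
    # chord length from a point on the sphere: t = -2 (p0 . u)
    t = -2.0 * np.einsum("ij,ij->i", p0, u)
    q = p0 + t[:, None] * u
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)

    # photons heading back out of the entry port strike the sample
    back = ~into
    if sample_port_label in phi_n:
        np.add.at(phi_n[sample_port_label], bins[back], w[back])
    else:
        np.add.at(wall, bins[back], w[back])

    if azimuthal_average:
        theta_q = np.arccos(np.clip(qn[into, 2], -1.0, 1.0))
        w_in = w[into]
        b_in = bins[into]
        remaining = np.ones(theta_q.size)
        theta_fov = np.arccos(np.clip(geometry.fov_direction[2], -1.0, 1.0))
        f = _cap_band_fraction(
            theta_q, theta_fov, geometry.cap_cos_half_angle(geometry.fov_area_mm2)
        )
        np.add.at(phi_d0, b_in, w_in * f)
        remaining -= f
        for s in geometry.surfaces:
            theta_s = np.arccos(np.clip(s.direction[2], -1.0, 1.0))
            f = _cap_band_fraction(
                theta_q, theta_s, geometry.cap_cos_half_angle(s.area_mm2)
            )
            np.add.at(phi_n[s.label], b_in, w_in * f)
            remaining -= f
        np.add.at(wall, b_in, w_in * np.maximum(remaining, 0.0))
    else:
        assigned = np.zeros(records.size, dtype=bool)
        assigned |= back

        # detector FOV first (exclusive assignment)
        cos_fov = geometry.cap_cos_half_angle(geometry.fov_area_mm2)
        hit = ~assigned & (qn @ geometry.fov_direction >= cos_fov)
        np.add.at(phi_d0, bins[hit], w[hit])
        assigned |= hit

        for s in geometry.surfaces:
            cos_cap = geometry.cap_cos_half_angle(s.area_mm2)
            hit = ~assigned & (qn @ s.direction >= cos_cap)
            np.add.at(phi_n[s.label], bins[hit], w[hit])
            assigned |= hit

        np.add.at(wall, bins[~assigned], w[~assigned])

    out = {label: Spectrum(grid, v) for label, v in phi_n.items()}
    out["wall"] = Spectrum(grid, wall)
    return Spectrum(grid, phi_d0), out


def detected_flux(
    phi_d0: Spectrum,
    phi_n: dict[str, Spectrum],
    geometry: SphereGeometry,
    sample_rho: np.ndarray | None = None,
) -> Spectrum:
    """Analytic sphere model: direct FOV light plus the diffuse-mixing series."""
    grid = phi_d0.grid
    asph = geometry.sphere_area_mm2
    adet = geometry.detector_area_mm2

    rho = {"wall": geometry.wall_rho_on(grid)}
    area = {"wall": geometry.wall_area_mm2}
    for s in geometry.surfaces:
        rho[s.label] = s.rho_on(grid, sample_rho)
        area[s.label] = s.area_mm2

    beta = np.zeros(grid.n_bins)
    for label in rho:
        beta += rho[label] * area[label] / asph
    if np.any(beta >= 1.0):
        raise ValueError("non-physical sphere gain: sum rho_l A_l / A_sph >= 1")

    first_bounce = np.zeros(grid.n_bins)
    for label, spec in phi_n.items():
        if spec.grid != grid:
            raise ValueError("grid mismatch in surface irradiations")
        if label not in rho:
            raise KeyError(f"irradiated surface {label!r} not in the geometry")
        first_bounce += rho[label] * spec.values

    values = phi_d0.values + (adet / asph) * first_bounce / (1.0 - beta)
    return Spectrum(grid, values)


def sample_diffuse_reflectance(
    sample: LayeredSample, n_photons: int, seed: int
) -> np.ndarray:
    """Per-wavelength sample reflectance under cosine-distributed incidence.

    Auxiliary Monte Carlo run feeding the sphere model's sample-linked
    surface: the diffusely mixed sphere field re-illuminates the sample
    quasi-isotropically, approximated by a Lambertian source.  The
    fluorescence branch is disabled so rho is the elastic (same-wavelength)
    return fraction.
    """
    if n_photons <= 0:
        raise ValueError("need at least one photon")
    tallies = run_forward(
        sample,
        None,
        n_photons,
        seed,
        beam="cosine",
        fluorescence=False,
        source_mode="stratified",
    )
    launched = np.maximum(tallies.launched_per_bin, 1)
    return tallies.reflectance_spectrum.values / launched


# ---------------------------------------------------------------------------
# source inversion
# ---------------------------------------------------------------------------


def invert_source_transmission(phi_d: Spectrum, geometry: SphereGeometry) -> Spectrum:
    """Recover the source spectrum from an open-port transmission reading.

    Assumes no direct FOV excitation and wall-only irradiation:
    Phi_s = Phi_D * A_sph * (1 - rho_wall A_wall / A_sph) / (A_det rho_wall).
    """
    grid = phi_d.grid
    rho_w = geometry.wall_rho_on(grid)
    if np.any((phi_d.values > 0) & (rho_w <= 0)):
        raise ValueError("rho_wall = 0 where the detector reads nonzero signal")
    asph = geometry.sphere_area_mm2
    fac = np.zeros(grid.n_bins)
    ok = rho_w > 0
    fac[ok] = (
        asph
        * (1.0 - rho_w[ok] * geometry.wall_area_mm2 / asph)
        / (geometry.detector_area_mm2 * rho_w[ok])
    )
    return Spectrum(grid, phi_d.values * fac)


def invert_source_reflectance(phi_d: Spectrum, geometry: SphereGeometry) -> Spectrum:
    """Recover the source spectrum in the mirror-folded reflectance geometry.

    Phi_s = Phi_D * (A_sph/A_det) *
            (1 - rho_wall A_wall / A_sph + rho_mirror A_mirror / A_sph) / rho_mirror.
    """
    grid = phi_d.grid
    mirror = next((s for s in geometry.surfaces if s.kind == "mirror"), None)
    if mirror is None:
        raise ValueError("geometry has no mirror surface")
    rho_m = mirror.rho_on(grid, None)
    if np.any(rho_m <= 0):
        raise ValueError("rho_mirror must be > 0")
    rho_w = geometry.wall_rho_on(grid)
    asph = geometry.sphere_area_mm2
    fac = (
        (asph / geometry.detector_area_mm2)
        * (
            1.0
            - rho_w * geometry.wall_area_mm2 / asph
            + rho_m * mirror.area_mm2 / asph
        )
        / rho_m
    )
    return Spectrum(grid, phi_d.values * fac)


# ---------------------------------------------------------------------------
# instrument function
# ---------------------------------------------------------------------------


def convolve_instrument(spectrum: Spectrum, irf: InstrumentFunction) -> Spectrum:
    """Exact discrete convolution with the instrument kernel on the grid."""
    k = irf.kernel
    if k.size > spectrum.values.size:
        raise ValueError("kernel wider than the spectrum support")
    return Spectrum(spectrum.grid, np.convolve(spectrum.values, k, mode="same"))


def deconvolve_instrument(
    spectrum: Spectrum,
    irf: InstrumentFunction,
    max_iter: int = 50,
    rtol: float = 1e-6,
) -> Spectrum:
    """Iterative non-negative (Richardson-Lucy) instrument deconvolution.

    Fixed iteration cap with early stop on relative change; the restored
    spectrum re-convolved with the kernel approximates the input.
    """
    y = np.asarray(spectrum.values, dtype=float)
    if np.any(y < 0):
        raise ValueError("spectrum must be non-negative")
    k = irf.kernel
    if k.size > y.size:
        raise ValueError("kernel wider than the spectrum support")
    if k.size == 1:
        return Spectrum(spectrum.grid, y / k[0])
    k_flip = k[::-1]
    d = np.maximum(y, 1e-30)
    eps = 1e-30
    for _ in range(max_iter):
        blurred = np.convolve(d, k, mode="same")
        ratio = y / np.maximum(blurred, eps)
        d_new = d * np.convolve(ratio, k_flip, mode="same")
        change = np.linalg.norm(d_new - d) / max(np.linalg.norm(d), eps)
        d = d_new
        if change < rtol:
            break
    return Spectrum(spectrum.grid, d)


# ---------------------------------------------------------------------------
# full detection chain
# ---------------------------------------------------------------------------


def _reflectance_frame(records: np.ndarray) -> np.ndarray:
    """Flip z so reflectance-side exits point into their sphere."""
    out = records.copy()
    out["uz"] = -out["uz"]
    return out


def simulate_detected_spectra(
    sample: LayeredSample,
    source: Spectrum,
    geometry_r: SphereGeometry,
    geometry_t: SphereGeometry,
    n_photons: int,
    seed: int,
    irf: InstrumentFunction | None = None,
    rho_sample: np.ndarray | None = None,
    aux_photons: int | None = None,
    tallies: TallySet | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Detected reflectance and transmission spectra of the digital twin.

    Runs the forward cascade, splits the exit records into each sphere,
    applies the analytic detection model (the reflectance geometry carries
    the fold mirror and the sample-linked reflectance), and convolves with
    the instrument function.  Spectra are normalized to the incident radiant
    power (source total over launched photons), so the result is independent
    of the photon budget up to Monte Carlo noise.  Deterministic for a fixed
    seed.
    """
    grid = sample.grid
    if rho_sample is None:
        aux = aux_photons if aux_photons is not None else max(n_photons // 4, 10_000)
        rho_sample = sample_diffuse_reflectance(sample, aux, (seed * 31 + 7) % 2**31)
    if tallies is None:
        tallies = run_forward(sample, source, n_photons, seed)
    power_per_photon = source.total / tallies.launched

    detected = {}
    for side, geometry in (("reflectance", geometry_r), ("transmission", geometry_t)):
        records = tallies.records(side)
        if side == "reflectance":
            records = _reflectance_frame(records)
        phi_d0, phi_n = irradiation_split(
            records, geometry, grid, azimuthal_average=True
        )
        spec = detected_flux(phi_d0, phi_n, geometry, sample_rho=rho_sample)
        spec = Spectrum(grid, spec.values * power_per_photon)
        if irf is not None:
            spec = convolve_instrument(spec, irf)
        detected[side] = spec
    return detected["reflectance"], detected["transmission"]
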