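"""Forward Monte Carlo solver of the fluorescence radiative transfer equation.

Photons are launched from a source spectrum onto a layered slab (z = 0 at
the illuminated face), propagated with exponential free paths through the
wavelength-dependent extinction of the layer mixture, scattered by
Henyey-Greenstein deflections, absorbed per component, and re-emitted
isotropically with a new wavelength drawn from the fluorophore's intrinsic
emission distribution.  The full re-absorption/re-emission cascade is
followed until every photon escapes or is terminally absorbed.

The per-event operations (`sample_free_path`, `choose_interaction`,
`sample_scatter`, `boundary_interaction`, `absorb_or_fluoresce`) are exposed
as pure functions of explicit uniform deviates; `run_forward` executes the
compiled kernel over N photons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .emission import EmissionGMM
from .spectral import (
    ComponentOpticalProperties,
    LayeredSample,
    MixtureCoefficients,
    SpectralGrid,
    Spectrum,
)

__all__ = [
    "Photon",
    "TallySet",
    "Interaction",
    "YieldMode",
    "launch_photon",
    "sample_free_path",
    "choose_interaction",
    "absorb_or_fluoresce",
    "sample_scatter",
    "boundary_interaction",
    "run_forward",
    "estimate_quantum_yield",
]

EXIT_RECORD_DTYPE = np.dtype(
    [
        ("side", np.int8),  # 1 reflectance (z < 0), 2 transmission (z > bottom)
        ("x", float),
        ("y", float),
        ("ux", float),
        ("uy", float),
        ("uz", float),
        ("lam", float),
        ("weight", float),
        ("n_cycles", np.int32),
    ]
)


class Interaction(enum.Enum):
    ABSORB = "absorb"
    SCATTER = "scatter"


class YieldMode(enum.Enum):
    INTRINSIC_DEF = "intrinsic"
    UNCORRECTED = "uncorrected"
    GROSS = "gross"


@dataclass
class Photon:
    """Monte Carlo photon state."""

    position: np.ndarray  # (x, y, z) mm
    direction: np.ndarray  # unit vector
    lam: float  # nm
    weight: float = 1.0
    n_cycles: int = 0
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class TallySet:
    """All outputs of a forward run.

    Integer conservation holds exactly:
    ``launched == n_escaped + n_absorbed + n_trapped`` (``n_trapped`` is the
    count of photons stopped by the per-photon event cap; zero on all
    physically sensible configurations).
    """

    grid: SpectralGrid
    launched: int
    launched_per_bin: np.ndarray
    reflectance_spectrum: Spectrum
    transmission_spectrum: Spectrum
    exit_records: np.ndarray  # EXIT_RECORD_DTYPE, escaping photons only
    component_names: list[str]
    term_abs_count: np.ndarray  # (C, 2): [:, 0] primary, [:, 1] secondary
    term_abs_weight: np.ndarray
    n_emission_events: int
    n_fluo_abs_events: int
    n_primary_fluo_abs: int
    n_primary_any_abs: int
    n_trapped: int
    seed: int = 0

    @property
    def n_escaped(self) -> int:
        return int(self.exit_records.size)

    @property
    def n_absorbed(self) -> int:
        return int(self.term_abs_count.sum())

    def conservation_holds(self) -> bool:
        return self.launched == self.n_escaped + self.n_absorbed + self.n_trapped

    def records(self, side: str) -> np.ndarray:
        code = {"reflectance": 1, "transmission": 2}[side]
        return self.exit_records[self.exit_records["side"] == code]


# ---------------------------------------------------------------------------
# per-event operations
# ---------------------------------------------------------------------------


def launch_photon(source: Spectrum, beam: str, xis: tuple[float, ...]) -> Photon:
    """Initialize a photon: wavelength from the source inverse CDF, beam geometry.

    ``beam`` is ``'pencil'`` (collimated, normal incidence at the origin) or
    ``'cosine'`` (Lambertian incidence).  ``xis`` supplies the uniform
    deviates: (xi_lambda,) for a pencil beam, (xi_lambda, xi_z, xi_phi) for
    cosine incidence.
    """
    if source.total <= 0:
        raise ValueError("zero-power source")
    cdf = source.cdf_on_edges()
    lam = float(np.interp(xis[0], cdf, source.grid.bin_edges))
    if beam == "pencil":
        direction = np.array([0.0, 0.0, 1.0])
    elif beam == "cosine":
        uz = np.sqrt(xis[1])
        sr = np.sqrt(max(0.0, 1.0 - uz * uz))
        phi = 2.0 * np.pi * xis[2]
        direction = np.array([sr * np.cos(phi), sr * np.sin(phi), uz])
    else:
        raise ValueError(f"unknown beam geometry {beam!r}")
    return Photon(position=np.zeros(3), direction=direction, lam=lam)


def sample_free_path(mu_t: float, xi: float) -> float:
    """Exponential free path s = -ln(1 - xi) / mu_t; unbounded when mu_t = 0."""
    if mu_t < 0:
        raise ValueError("mu_t must be >= 0")
    if mu_t == 0:
        return np.inf
    return -np.log1p(-xi) / mu_t


def choose_interaction(mu_a_tot: float, mu_s_tot: float, xi: float) -> Interaction:
    """Absorb iff xi < mu_a / (mu_a + mu_s)."""
    mu_t = mu_a_tot + mu_s_tot
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be > 0 at an interaction site")
    return Interaction.ABSORB if xi < mu_a_tot / mu_t else Interaction.SCATTER


def absorb_or_fluoresce(
    photon: Photon,
    coeffs: MixtureCoefficients,
    components: list[ComponentOpticalProperties],
    xi0: float,
    xi1: float,
    xi2: float,
    xi3: float,
    xi_lam: float,
):
    """Resolve an absorption event: terminal absorption or re-emission.

    The absorbing component is selected by cumulative mu_a fractions (base
    components pooled first, then fluorescent ones, mirroring the additive
    mixture).  A fluorophore re-emits iff ``xi1 <= phi_f``; re-emission draws
    a new wavelength from the emission CDF, multiplies the weight by
    ``lam_old / lam_new``, resets the direction isotropically
    (cos(theta) = 1 - 2*xi2, phi = 2*pi*xi3), and increments the cycle count.

    Returns ``('terminated', component_name)`` or ``('reemitted', photon)``.
    """
    fluo_comps = [c for c in components if c.is_fluorescent]
    if len(fluo_comps) != coeffs.mu_a_fluo.size:
        raise ValueError("components do not match the coefficient set")
    mu_a_tot = coeffs.mu_a_total
    if mu_a_tot <= 0:
        raise ValueError("no absorption at this wavelength")
    target = xi0 * mu_a_tot
    if target < coeffs.mu_a_base:
        base_names = [c.name for c in components if not c.is_fluorescent]
        photon.alive = False
        return ("terminated", base_names[0] if base_names else "base")
    acc = coeffs.mu_a_base
    comp = fluo_comps[-1]
    for c, mu in zip(fluo_comps, coeffs.mu_a_fluo):
        acc += mu
        if target < acc:
            comp = c
            break
    if not (0.0 <= comp.phi_f <= 1.0):
        raise ValueError("phi_f outside [0, 1]")
    if xi1 > comp.phi_f:
        photon.alive = False
        return ("terminated", comp.name)
    lam_old = photon.lam
    lam_new = float(comp.emission.sample(xi_lam))
    photon.weight *= lam_old / lam_new
    photon.lam = lam_new
    cos_t = 1.0 - 2.0 * xi2
    sr = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * np.pi * xi3
    photon.direction = np.array([sr * np.cos(phi), sr * np.sin(phi), cos_t])
    photon.n_cycles += 1
    return ("reemitted", photon)


def sample_scatter(
    mu_s: np.ndarray,
    g: np.ndarray,
    direction: np.ndarray,
    xi: float,
    xi_theta: float,
    xi_phi: float,
) -> np.ndarray:
    """New direction after a scattering event.

    The scattering component is chosen by cumulative mu_s fractions; the
    deflection cosine comes from the analytic Henyey-Greenstein inverse CDF
    of that component's g.
    """
    mu_s = np.asarray(mu_s, dtype=float)
    g = np.asarray(g, dtype=float)
    tot = mu_s.sum()
    if tot <= 0:
        raise ValueError("mu_s_tot must be > 0 to scatter")
    if np.any(np.abs(g) >= 1):
        raise ValueError("|g| must be < 1")
    target = xi * tot
    j = min(int(np.searchsorted(np.cumsum(mu_s), target, side="right")), mu_s.size - 1)
    cos_t = _kernel.hg_cos_theta(float(g[j]), xi_theta)
    phi = 2.0 * np.pi * xi_phi
    ux, uy, uz = _kernel.rotate_direction(
        float(direction[0]), float(direction[1]), float(direction[2]), cos_t, phi
    )
    return np.array([ux, uy, uz])


def boundary_interaction(
    direction: np.ndarray, n1: float, n2: float, xi: float
) -> tuple[str, np.ndarray]:
    """Unpolarized Fresnel decision at a z-normal interface.

    Returns ``('reflected', dir)`` or ``('refracted', dir)``; total internal
    reflection always reflects.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be > 0")
    ux, uy, uz = (float(v) for v in direction)
    R, cos_t = _kernel.fresnel_unpolarized(n1, n2, abs(uz))
    if xi < R:
        return ("reflected", np.array([ux, uy, -uz]))
    scale = n1 / n2
    sign = 1.0 if uz >= 0 else -1.0
    return ("refracted", np.array([ux * scale, uy * scale, sign * cos_t]))


# ---------------------------------------------------------------------------
# full forward run
# ---------------------------------------------------------------------------


def _compile_sample(sample: LayeredSample):
    """Flatten a LayeredSample into the dense arrays the kernel consumes."""
    grid = sample.grid
    nbins = grid.n_bins
    comps: list[ComponentOpticalProperties] = []
    for layer in sample.layers:
        for comp, _ in layer.components:
            if all(comp is not c for c in comps):
                comps.append(comp)
    n_comp = max(len(comps), 1)
    n_layers = len(sample.layers)

    mua = np.zeros((n_layers, n_comp, nbins))
    mus = np.zeros((n_layers, n_comp, nbins))
    gg = np.zeros((n_layers, n_comp, nbins))
    for li, layer in enumerate(sample.layers):
        for comp, w in layer.components:
            ci = next(k for k, c in enumerate(comps) if c is comp)
            mua[li, ci] += w * comp.mu_a
            mus[li, ci] += w * comp.mu_s
            gg[li, ci] = comp.g

    n_stack = np.empty((n_layers + 2, nbins))
    n_stack[0] = sample.ambient_index_on("above")
    for li, layer in enumerate(sample.layers):
        n_stack[li + 1] = layer.index_on(grid)
    n_stack[-1] = sample.ambient_index_on("below")

    fluo = [c for c in comps if c.is_fluorescent]
    comp_fluo = np.full(n_comp, -1, dtype=np.int64)
    for ci, c in enumerate(comps):
        if c.is_fluorescent:
            comp_fluo[ci] = next(k for k, f in enumerate(fluo) if f is c)
    phi_f = np.array([c.phi_f for c in fluo], dtype=float)
    if fluo:
        for c in fluo:
            lo, hi = c.emission.support
            if lo < grid.lo or hi > grid.hi:
                raise ValueError(
                    f"emission support of {c.name!r} exceeds the simulation grid"
                )
        em_icdf = np.stack([c.emission.icdf_table() for c in fluo])
    else:
        em_icdf = np.zeros((1, 2))
        phi_f = np.zeros(1)

    names = [c.name for c in comps] if comps else ["<empty>"]
    return comps, names, sample.z_bounds, n_stack, mua, mus, gg, comp_fluo, phi_f, em_icdf


def run_forward(
    sample: LayeredSample,
    source: Spectrum | None,
    n_photons: int,
    seed: int,
    beam: str = "pencil",
    fluorescence: bool = True,
    source_mode: str = "spectrum",
    max_events: int = 200_000,
) -> TallySet:
    """Trace ``n_photons`` through the sample; bit-reproducible for a fixed seed.

    ``source_mode='stratified'`` ignores the source shape and launches equal
    photon counts into every wavelength bin (used by the auxiliary
    diffuse-reflectance run, which needs uniform per-bin statistics).
    """
    grid = sample.grid
    if source_mode == "spectrum":
        if source is None:
            raise ValueError("a source spectrum is required")
        if source.grid != grid:
            raise ValueError("source grid must match the sample grid")
        src_cdf = source.cdf_on_edges()
        src_mode = 0
    elif source_mode == "stratified":
        src_cdf = np.linspace(0.0, 1.0, grid.n_bins + 1)
        src_mode = 1
    else:
        raise ValueError(f"unknown source_mode {source_mode!r}")

    beam_mode = {"pencil": 0, "cosine": 1}[beam]
    (
        comps,
        names,
        z_bounds,
        n_stack,
        mua,
        mus,
        gg,
        comp_fluo,
        phi_f,
        em_icdf,
    ) = _compile_sample(sample)

    out = _kernel.trace_photons(
        np.uint64(seed),
        int(n_photons),
        grid.bin_edges,
        src_cdf,
        src_mode,
        np.asarray(z_bounds, dtype=float),
        n_stack,
        mua,
        mus,
        gg,
        comp_fluo,
        phi_f,
        em_icdf,
        1 if fluorescence else 0,
        beam_mode,
        int(max_events),
    )
    (
        refl_w,
        trans_w,
        launched_per_bin,
        exit_side,
        exit_x,
        exit_y,
        exit_ux,
        exit_uy,
        exit_uz,
        exit_lam,
        exit_w,
        exit_ncyc,
        term_count,
        term_weight,
        n_emission,
        n_fluo_abs,
        n_prim_fluo,
        n_prim_any,
        n_trapped,
    ) = out

    mask = exit_side > 0
    records = np.zeros(int(mask.sum()), dtype=EXIT_RECORD_DTYPE)
    records["side"] = exit_side[mask]
    records["x"] = exit_x[mask]
    records["y"] = exit_y[mask]
    records["ux"] = exit_ux[mask]
    records["uy"] = exit_uy[mask]
    records["uz"] = exit_uz[mask]
    records["lam"] = exit_lam[mask]
    records["weight"] = exit_w[mask]
    records["n_cycles"] = exit_ncyc[mask]

    tallies = TallySet(
        grid=grid,
        launched=int(n_photons),
        launched_per_bin=launched_per_bin,
        reflectance_spectrum=Spectrum(grid, refl_w),
        transmission_spectrum=Spectrum(grid, trans_w),
        exit_records=records,
        component_names=names,
        term_abs_count=term_count,
        term_abs_weight=term_weight,
        n_emission_events=int(n_emission),
        n_fluo_abs_events=int(n_fluo_abs),
        n_primary_fluo_abs=int(n_prim_fluo),
        n_primary_any_abs=int(n_prim_any),
        n_trapped=int(n_trapped),
        seed=int(seed),
    )
    if not tallies.conservation_holds():  # pragma: no cover - kernel invariant
        raise AssertionError(
            "photon conservation violated: "
            f"launched={tallies.launched} escaped={tallies.n_escaped} "
            f"absorbed={tallies.n_absorbed} trapped={tallies.n_trapped}"
        )
    return tallies


def estimate_quantum_yield(tallies: TallySet, mode: YieldMode | str) -> float:
    """Photon-count quantum-yield estimators on a completed run.

    INTRINSIC_DEF: re-emission events / all absorption events in fluorescent
    components (the defining emitted-to-absorbed ratio).  UNCORRECTED:
    escaping photons that underwent >= 1 emission cycle / primary absorption
    events in fluorescent components (what an ideal loss-free detector would
    report).  GROSS: same numerator / primary absorption events in any
    component (fluorophore absorption not disambiguated).
    """
    if isinstance(mode, str):
        mode = YieldMode(mode)
    if mode is YieldMode.INTRINSIC_DEF:
        denom = tallies.n_fluo_abs_events
        numer = tallies.n_emission_events
    else:
        numer = int(np.count_nonzero(tallies.exit_records["n_cycles"] >= 1))
        denom = (
            tallies.n_primary_fluo_abs
            if mode is YieldMode.UNCORRECTED
            else tallies.n_primary_any_abs
        )
    if denom == 0:
        raise ZeroDivisionError(f"no denominator events for {mode}")
    return numer / denom
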