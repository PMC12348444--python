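"""Integrating-sphere twin: irradiation split, the analytic detection model
against a brute-force Lambertian bounce tracer, source inversions, and the
instrument-function round trip."""

import numpy as np
import pytest

from fluocascade import fixtures
from fluocascade.spectral import SpectralGrid, Spectrum
from fluocascade.sphere import (
    InstrumentFunction,
    SphereGeometry,
    SphereSurface,
    convolve_instrument,
    deconvolve_instrument,
    detected_flux,
    invert_source_reflectance,
    invert_source_transmission,
    irradiation_split,
    sample_diffuse_reflectance,
)
from fluocascade.transport import EXIT_RECORD_DTYPE


def small_grid():
    return SpectralGrid.default(500, 510, 1.0)


def records_from(directions, lam=505.0, weight=1.0):
    rec = np.zeros(len(directions), dtype=EXIT_RECORD_DTYPE)
    rec["side"] = 2
    rec["ux"], rec["uy"], rec["uz"] = np.asarray(directions, float).T
    rec["lam"] = lam
    rec["weight"] = weight
    return rec


# ---------------------------------------------------------------------------
# brute-force Lambertian bounce tracer (test oracle, built before the model)
# ---------------------------------------------------------------------------


def lambertian_bounce_trace(geometry, phi_n, n_rays=200_000, seed=0, max_bounces=4000):
    """Monte Carlo reference for the diffuse-mixing series.

    Starts weight on each irradiated surface, then repeatedly: absorb with
    (1 - rho), otherwise re-emit Lambertian.  For a point emitter on a sphere
    wall, Lambertian emission illuminates the sphere surface uniformly, so a
    bounce lands uniformly in area; the landing patch is classified by cap
    geometry.  The detector accumulates (A_det / A_sph) of every re-emitted
    generation.  This reproduces the geometric series bounce-by-bounce
    without using the closed form.
    """
    rng = np.random.default_rng(seed)
    asph = geometry.sphere_area_mm2
    adet = geometry.detector_area_mm2
    rho = {"wall": float(np.mean(geometry.wall_rho_on(small_grid())))}
    area = {"wall": geometry.wall_area_mm2}
    for s in geometry.surfaces:
        rho[s.label] = float(np.mean(s.rho_on(small_grid(), None)))
        area[s.label] = s.area_mm2
    labels = list(rho)
    rho_arr = np.array([rho[l] for l in labels])
    landing_cdf = np.cumsum([area[l] for l in labels])
    landing_cdf = landing_cdf / landing_cdf[-1] * (1.0 - adet / asph)

    detected = 0.0
    for label, phi in phi_n.items():
        if phi == 0:
            continue
        w = phi / n_rays
        state = np.full(n_rays, labels.index(label))
        for _ in range(max_bounces):
            # absorb with (1 - rho) at the current surface
            alive = rng.random(state.size) < rho_arr[state]
            state = state[alive]
            if state.size == 0:
                break
            # every surviving re-emission is Lambertian: the detector sees
            # its area share, the rest lands uniformly in area
            detected += w * state.size * adet / asph
            u = rng.random(state.size) * (1.0 - adet / asph)
            state = np.searchsorted(landing_cdf, u)
    return detected


def series_geometry(rho_wall, surfaces=()):
    return SphereGeometry(
        diameter_mm=150.0,
        wall_reflectance=rho_wall,
        detector_area_mm2=50.0,
        fov_area_mm2=100.0,
        fov_direction=np.array([0.0, 0.0, 1.0]),
        surfaces=list(surfaces),
    )


class TestDetectedFlux:
    def test_black_sphere_passes_only_direct_light(self):
        grid = small_grid()
        geom = series_geometry(0.0)
        phi_d0 = Spectrum(grid, np.full(grid.n_bins, 0.3))
        phi_n = {"wall": Spectrum(grid, np.ones(grid.n_bins))}
        out = detected_flux(phi_d0, phi_n, geom)
        np.testing.assert_allclose(out.values, 0.3, rtol=1e-14)

    def test_single_wall_geometric_series_closed_form(self):
        """rho=0.5 with the wall as the whole sphere: Phi_D = f 0.5/(1-0.5)."""
        grid = small_grid()
        geom = series_geometry(0.5)
        f = geom.detector_area_mm2 / geom.sphere_area_mm2
        phi_n = {"wall": Spectrum(grid, np.ones(grid.n_bins))}
        out = detected_flux(Spectrum(grid, np.zeros(grid.n_bins)), phi_n, geom)
        beta = 0.5 * geom.wall_area_mm2 / geom.sphere_area_mm2
        np.testing.assert_allclose(out.values, f * 0.5 / (1 - beta), rtol=1e-12)

    def test_nonphysical_gain_rejected(self):
        grid = small_grid()
        geom = series_geometry(1.0)  # rho A / A_sph -> ~1
        phi_n = {"wall": Spectrum(grid, np.ones(grid.n_bins))}
        with pytest.raises(ValueError, match="gain"):
            detected_flux(Spectrum(grid, np.zeros(grid.n_bins)), phi_n, geom)

    @pytest.mark.parametrize(
        "rho_wall,extra",
        [
            (0.90, ()),
            (0.95, (("portA", 600.0, 0.0), ("mirror", 150.0, 0.9))),
            (0.80, (("portA", 300.0, 0.0), ("portB", 300.0, 0.0), ("patch", 500.0, 0.5))),
        ],
    )
    def test_analytic_model_matches_lambertian_bounce_tracer(self, rho_wall, extra):
        grid = small_grid()
        surfaces = [
            SphereSurface(lbl, a, r, np.array([1.0, 0.0, 0.0]))
            for (lbl, a, r) in extra
        ]
        geom = series_geometry(rho_wall, surfaces)
        phi_n_spec = {"wall": Spectrum(grid, np.ones(grid.n_bins))}
        for s in surfaces:
            phi_n_spec[s.label] = Spectrum(grid, np.full(grid.n_bins, 0.5))
        analytic = detected_flux(
            Spectrum(grid, np.zeros(grid.n_bins)), phi_n_spec, geom
        ).values[0]
        brute = lambertian_bounce_trace(
            geom,
            {lbl: s.values[0] for lbl, s in phi_n_spec.items()},
            n_rays=400_000,
            seed=123,
        )
        assert brute == pytest.approx(analytic, rel=0.01)


class TestIrradiationSplit:
    def test_open_port_absorbs_everything_aimed_at_it(self):
        grid = small_grid()
        port = SphereSurface("hole", 700.0, 0.0, np.array([0.0, 0.0, 1.0]))
        geom = SphereGeometry(
            wall_reflectance=0.95, detector_area_mm2=50.0, fov_area_mm2=100.0,
            fov_direction=np.array([1.0, 0.0, 0.0]), surfaces=[port],
        )
        rec = records_from([[0.0, 0.0, 1.0]] * 50)  # straight up: north-pole cap
        phi_d0, phi_n = irradiation_split(rec, geom, grid)
        assert phi_d0.total == 0.0
        assert phi_n["hole"].total == pytest.approx(50.0)
        assert phi_n["wall"].total == 0.0

    def test_split_conserves_total_exit_weight(self, rng):
        grid = small_grid()
        geom = fixtures.make_sphere_geometry(with_mirror=True)
        n = 5000
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rec = records_from(u, weight=1.0)
        rec["weight"] = rng.random(n) + 0.5
        rec["x"] = rng.uniform(-30, 30, n)
        rec["y"] = rng.uniform(-30, 30, n)
        phi_d0, phi_n = irradiation_split(rec, geom, grid)
        assigned = phi_d0.total + sum(s.total for s in phi_n.values())
        assert assigned == pytest.approx(rec["weight"].sum(), rel=1e-12)

    def test_azimuthal_average_matches_binary_split_in_expectation(self):
        """The azimuth-averaged split conserves weight exactly and agrees
        with the binary classification on azimuth-symmetric record sets."""
        rng = np.random.default_rng(987654)
        grid = small_grid()
        geom = fixtures.make_sphere_geometry(with_mirror=True)
        n = 400_000
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rec = records_from(u)
        d0_b, pn_b = irradiation_split(rec, geom, grid)
        d0_a, pn_a = irradiation_split(rec, geom, grid, azimuthal_average=True)
        total = rec["weight"].sum()
        assert d0_a.total + sum(s.total for s in pn_a.values()) == pytest.approx(
            total, rel=1e-12
        )
        # the binary counts are binomial; compare at 4 standard errors
        for binary, averaged in [(d0_b.total, d0_a.total)] + [
            (pn_b[l].total, pn_a[l].total) for l in pn_b if pn_b[l].total > 300
        ]:
            se = np.sqrt(binary)
            assert abs(averaged - binary) < 4 * se

    def test_lambertian_entry_weights_surfaces_by_area(self, rng):
        """Cosine-distributed entry from a wall point irradiates the sphere
        uniformly in area - the classic integrating-sphere property."""
        grid = small_grid()
        cap = SphereSurface("cap", 3000.0, 0.0, np.array([0.0, 0.0, 1.0]))
        geom = SphereGeometry(
            wall_reflectance=0.95, detector_area_mm2=50.0, fov_area_mm2=800.0,
            fov_direction=np.array([1.0, 0.0, 0.0]), surfaces=[cap],
        )
        n = 400_000
        uz = np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        sr = np.sqrt(1 - uz**2)
        rec = records_from(np.column_stack([sr * np.cos(phi), sr * np.sin(phi), uz]))
        phi_d0, phi_n = irradiation_split(rec, geom, grid)
        asph = geom.sphere_area_mm2
        got_cap = phi_n["cap"].total / n
        got_fov = phi_d0.total / n
        for got, area in ((got_cap, cap.area_mm2), (got_fov, geom.fov_area_mm2)):
            expect = area / asph
            assert abs(got - expect) < 3 * np.sqrt(expect * (1 - expect) / n)


class TestSampleReflectance:
    def test_vacuum_sample_returns_nothing(self, grid):
        from fluocascade.spectral import Layer, LayeredSample

        empty = LayeredSample(grid, [Layer(4.0, 1.0, [])])
        rho = sample_diffuse_reflectance(empty, 20_000, seed=3)
        assert np.all(rho == 0.0)

    def test_thick_nonabsorbing_scatterer_approaches_unit_reflectance(self, grid, fixture_spec):
        scat = fixtures.make_scatterer(fixture_spec, grid)
        last = 0.0
        for d in (2.0, 20.0):
            slab = fixtures.make_bare_slab([(scat, 1.0)], grid, thickness_mm=d)
            rho = sample_diffuse_reflectance(slab, 20_000, seed=5)
            mean_rho = rho.mean()
            assert mean_rho > last
            last = mean_rho
        assert last > 0.9


class TestSourceInversion:
    def _geom_open(self, with_mirror=False):
        surfaces = [
            SphereSurface("portA", 400.0, 0.0, np.array([1.0, 0.0, 0.0])),
            SphereSurface("portB", 300.0, 0.0, np.array([-1.0, 0.0, 0.0])),
        ]
        if with_mirror:
            surfaces.append(
                SphereSurface("mirror", 120.0, 0.9, np.array([0.0, 1.0, 0.0]), kind="mirror")
            )
        return series_geometry(0.93, surfaces)

    def test_transmission_inversion_is_exact_algebraic_inverse(self):
        grid = small_grid()
        geom = self._geom_open()
        phi_s = Spectrum(grid, np.linspace(1.0, 2.0, grid.n_bins))
        # forward: wall-only irradiation, no direct FOV light
        rho_w = geom.wall_rho_on(grid)
        asph = geom.sphere_area_mm2
        phi_d = Spectrum(
            grid,
            (geom.detector_area_mm2 / asph)
            * rho_w * phi_s.values
            / (1.0 - rho_w * geom.wall_area_mm2 / asph),
        )
        back = invert_source_transmission(phi_d, geom)
        np.testing.assert_allclose(back.values, phi_s.values, rtol=1e-12)

    def test_zero_signal_inverts_to_zero_and_scales_linearly(self):
        grid = small_grid()
        geom = self._geom_open()
        zero = invert_source_transmission(Spectrum(grid, np.zeros(grid.n_bins)), geom)
        assert zero.total == 0.0
        phi_d = Spectrum(grid, np.full(grid.n_bins, 0.01))
        one = invert_source_transmission(phi_d, geom)
        two = invert_source_transmission(Spectrum(grid, 2 * phi_d.values), geom)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-14)

    def test_reflectance_inversion_round_trip(self):
        grid = small_grid()
        geom = self._geom_open(with_mirror=True)
        mirror = geom.find("mirror")
        rho_w = geom.wall_rho_on(grid)
        rho_m = mirror.rho_on(grid, None)
        asph = geom.sphere_area_mm2
        phi_s = Spectrum(grid, np.linspace(0.5, 1.5, grid.n_bins))
        denom = 1.0 - rho_w * geom.wall_area_mm2 / asph + rho_m * mirror.area_mm2 / asph
        phi_d = Spectrum(
            grid, phi_s.values * rho_m * geom.detector_area_mm2 / (asph * denom)
        )
        back = invert_source_reflectance(phi_d, geom)
        np.testing.assert_allclose(back.values, phi_s.values, rtol=1e-12)

    def test_degenerate_mirror_reduces_to_transmission_form(self):
        grid = small_grid()
        # a vanishing mirror with wall reflectance is just more wall: the
        # folded inversion then reduces to the open transmission form
        tiny = SphereSurface("mirror", 1e-9, 0.93, np.array([0.0, 1.0, 0.0]), kind="mirror")
        geom_m = series_geometry(0.93, [tiny])
        geom_o = series_geometry(0.93, [])
        phi_d = Spectrum(grid, np.full(grid.n_bins, 0.02))
        a = invert_source_reflectance(phi_d, geom_m)
        b = invert_source_transmission(phi_d, geom_o)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)


class TestInstrumentFunction:
    def test_delta_kernel_is_identity_both_ways(self, grid, source):
        irf = InstrumentFunction.delta()
        conv = convolve_instrument(source, irf)
        deconv = deconvolve_instrument(source, irf)
        np.testing.assert_allclose(conv.values, source.values, rtol=1e-14)
        np.testing.assert_allclose(deconv.values, source.values, rtol=1e-14)

    def test_convolution_preserves_the_integral(self, grid):
        irf = InstrumentFunction.gaussian(3.7)
        values = np.zeros(grid.n_bins)
        values[150:300] = np.hanning(150)
        spec = Spectrum(grid, values)
        conv = convolve_instrument(spec, irf)
        assert conv.total == pytest.approx(spec.total, rel=1e-9)

    def test_two_peak_spectrum_deconvolution_recovers_peak_positions(self, grid):
        """3.7 nm spectrometer blur on a two-peak spectrum is undone to 1 bin."""
        irf = InstrumentFunction.gaussian(3.7)
        values = np.zeros(grid.n_bins)
        lam = grid.centers
        values += 1.0 * np.exp(-0.5 * ((lam - 540.0) / 2.0) ** 2)
        values += 0.7 * np.exp(-0.5 * ((lam - 560.0) / 2.0) ** 2)
        truth = Spectrum(grid, values)
        blurred = convolve_instrument(truth, irf)
        restored = deconvolve_instrument(blurred, irf, max_iter=200, rtol=1e-9)
        peaks_truth = [540.0, 560.0]
        v = restored.values
        for peak in peaks_truth:
            window = (lam > peak - 8) & (lam < peak + 8)
            found = lam[window][np.argmax(v[window])]
            assert abs(found - peak) <= 1.0
        reblurred = convolve_instrument(restored, irf)
        assert np.max(np.abs(reblurred.values - blurred.values)) < 0.02 * v.max()

    def test_kernel_wider_than_spectrum_rejected(self):
        grid = SpectralGrid.default(500, 505, 1.0)
        spec = Spectrum(grid, np.ones(grid.n_bins))
        with pytest.raises(ValueError, match="wider"):
            convolve_instrument(spec, InstrumentFunction.gaussian(3.7))
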