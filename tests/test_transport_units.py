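"""Per-event transport operations: free paths, interaction choice, scattering
deflections, Fresnel boundaries, and the fluorescence weight update."""

import numpy as np
import pytest
from scipy import integrate

from fluocascade import _kernel
from fluocascade.spectral import SpectralGrid, Spectrum
from fluocascade.transport import (
    Interaction,
    Photon,
    absorb_or_fluoresce,
    boundary_interaction,
    choose_interaction,
    launch_photon,
    sample_free_path,
    sample_scatter,
)


class TestFreePath:
    def test_cdf_boundary_gives_zero_path(self):
        assert sample_free_path(2.0, 0.0) == 0.0

    def test_mean_of_exponential_sampling(self, rng):
        xi = rng.random(1_000_000)
        s = -np.log1p(-xi)  # mu_t = 1
        paths = np.array([sample_free_path(1.0, x) for x in xi[:1000]])
        np.testing.assert_allclose(paths, s[:1000], rtol=1e-12)
        # mean of the analytic transform over 1e6 draws: 1 +- 3 sigma
        assert abs(s.mean() - 1.0) < 3.0 / np.sqrt(s.size)

    def test_vacuum_gives_unbounded_step(self):
        assert sample_free_path(0.0, 0.7) == np.inf

    def test_negative_extinction_rejected(self):
        with pytest.raises(ValueError):
            sample_free_path(-1.0, 0.5)


class TestChooseInteraction:
    def test_equal_coefficients_absorb_below_half(self):
        assert choose_interaction(1.0, 1.0, 0.3) is Interaction.ABSORB
        assert choose_interaction(1.0, 1.0, 0.7) is Interaction.SCATTER

    def test_no_absorption_always_scatters(self, rng):
        assert all(
            choose_interaction(0.0, 1.0, xi) is Interaction.SCATTER
            for xi in rng.random(100)
        )

    def test_absorption_frequency_matches_probability(self, rng):
        xi = rng.random(1_000_000)
        freq = np.mean(xi < 0.25)  # mu_a=1, mu_s=3
        sigma = np.sqrt(0.25 * 0.75 / xi.size)
        assert abs(freq - 0.25) < 3 * sigma

    def test_zero_total_extinction_rejected(self):
        with pytest.raises(ValueError):
            choose_interaction(0.0, 0.0, 0.5)


class TestHenyeyGreenstein:
    def test_isotropic_limit_mean_cosine_zero(self, rng):
        xi = rng.random(1_000_000)
        cos = np.array([_kernel.hg_cos_theta(0.0, x) for x in xi[:2000]])
        np.testing.assert_allclose(cos, 2 * xi[:2000] - 1, rtol=1e-12)
        full = 2 * xi - 1
        assert abs(full.mean()) < 3 / np.sqrt(3 * full.size)  # var = 1/3

    def test_mean_cosine_equals_g_against_quadrature(self, rng):
        """First moment of the HG phase function is g (checked by quadrature),
        and the sampled mean cosine agrees within 3 standard errors."""
        g = 0.9

        def hg_pdf(c):
            return 0.5 * (1 - g * g) / (1 + g * g - 2 * g * c) ** 1.5

        first_moment, _ = integrate.quad(lambda c: c * hg_pdf(c), -1, 1)
        assert first_moment == pytest.approx(g, abs=1e-9)

        xi = rng.random(1_000_000)
        cos = (1 + g * g - ((1 - g * g) / (1 - g + 2 * g * xi)) ** 2) / (2 * g)
        spot = np.array([_kernel.hg_cos_theta(g, x) for x in xi[:2000]])
        np.testing.assert_allclose(spot, cos[:2000], rtol=1e-12)
        se = cos.std() / np.sqrt(cos.size)
        assert abs(cos.mean() - g) < 3 * se

    def test_quantile_value_against_numeric_cdf_inversion(self):
        """HG inverse CDF at (g=0.5, xi=0.5) agrees with brute-force inversion."""
        g = 0.5

        def hg_cdf(c):
            val, _ = integrate.quad(
                lambda t: 0.5 * (1 - g * g) / (1 + g * g - 2 * g * t) ** 1.5, -1, c
            )
            return val

        from scipy.optimize import brentq

        c_star = brentq(lambda c: hg_cdf(c) - 0.5, -1, 1, xtol=1e-12)
        got = _kernel.hg_cos_theta(0.5, 0.5)
        assert got == pytest.approx(c_star, abs=1e-9)
        assert got == pytest.approx(0.6875, abs=1e-9)


class TestSampleScatter:
    def test_direction_stays_normalized(self, rng):
        d = np.array([0.0, 0.0, 1.0])
        for _ in range(200):
            d = sample_scatter(
                np.array([1.0, 2.0]),
                np.array([0.3, 0.8]),
                d,
                rng.random(),
                rng.random(),
                rng.random(),
            )
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)

    def test_component_selection_by_cumulative_fractions(self):
        # xi = 0.2 with mu_s = (1, 3): first component covers [0, 0.25)
        d0 = np.array([0.0, 0.0, 1.0])
        d_a = sample_scatter(np.array([1.0, 3.0]), np.array([0.0, 0.9]), d0, 0.2, 0.5, 0.25)
        d_b = sample_scatter(np.array([1.0, 3.0]), np.array([0.0, 0.0]), d0, 0.2, 0.5, 0.25)
        np.testing.assert_allclose(d_a, d_b, atol=1e-12)  # both used g of comp 0

    def test_invalid_inputs_rejected(self):
        d0 = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            sample_scatter(np.array([0.0]), np.array([0.5]), d0, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            sample_scatter(np.array([1.0]), np.array([1.0]), d0, 0.5, 0.5, 0.5)


class TestBoundary:
    def test_index_matched_interface_is_transparent(self):
        kind, d = boundary_interaction(np.array([0.3, 0.0, np.sqrt(1 - 0.09)]), 1.5, 1.5, 0.999)
        assert kind == "refracted"
        np.testing.assert_allclose(d, [0.3, 0.0, np.sqrt(1 - 0.09)], atol=1e-12)

    def test_normal_incidence_fresnel_reflectance_is_four_percent(self):
        R, cos_t = _kernel.fresnel_unpolarized(1.0, 1.5, 1.0)
        assert R == pytest.approx(((1.0 - 1.5) / (1.0 + 1.5)) ** 2, abs=1e-15)
        assert cos_t == pytest.approx(1.0)

    def test_total_internal_reflection_beyond_critical_angle(self):
        # critical angle from n=1.5 to 1.0: sin = 1/1.5 -> uz below ~0.745
        d = np.array([0.8, 0.0, 0.6])
        kind, out = boundary_interaction(d, 1.5, 1.0, 0.999999)
        assert kind == "reflected"
        np.testing.assert_allclose(out, [0.8, 0.0, -0.6], atol=1e-12)

    def test_snell_refraction_preserves_transverse_scaling(self):
        d = np.array([0.5, 0.0, np.sqrt(0.75)])
        kind, out = boundary_interaction(d, 1.0, 1.5, 0.99)
        assert kind == "refracted"
        assert out[0] == pytest.approx(0.5 / 1.5)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_nonphysical_indices_rejected(self):
        with pytest.raises(ValueError):
            boundary_interaction(np.array([0.0, 0.0, 1.0]), -1.0, 1.5, 0.5)


class TestAbsorbOrFluoresce:
    def _photon(self, lam=500.0):
        return Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), lam)

    def _coeffs_and_comps(self, grid, dye, base_mu_a=0.0):
        from fluocascade.spectral import ComponentOpticalProperties, Layer, LayeredSample

        comps = [dye]
        pairs = [(dye, 1.0)]
        if base_mu_a > 0:
            solvent = ComponentOpticalProperties(
                "solvent", grid, np.full(grid.n_bins, base_mu_a),
                np.zeros(grid.n_bins), np.zeros(grid.n_bins),
            )
            comps.append(solvent)
            pairs.append((solvent, 1.0))
        sample = LayeredSample(grid, [Layer(1.0, 1.36, pairs)])
        return sample.mixture_coefficients(0, 500.0), comps

    def test_unit_quantum_yield_always_reemits(self, grid, dye, rng):
        bright = dye.with_fluorescence(1.0, dye.emission)
        coeffs, comps = self._coeffs_and_comps(grid, bright)
        for _ in range(50):
            outcome, _ = absorb_or_fluoresce(
                self._photon(), coeffs, comps, rng.random(), rng.random(),
                rng.random(), rng.random(), rng.random(),
            )
            assert outcome == "reemitted"

    def test_zero_quantum_yield_always_terminates(self, grid, dye, rng):
        dark = dye.with_fluorescence(0.0, dye.emission)
        coeffs, comps = self._coeffs_and_comps(grid, dark)
        for _ in range(50):
            outcome, name = absorb_or_fluoresce(
                self._photon(), coeffs, comps, rng.random(),
                max(rng.random(), 1e-12), rng.random(), rng.random(), rng.random(),
            )
            assert outcome == "terminated" and name == dye.name

    def test_stokes_weight_update_ratio(self, grid, dye):
        """A 500 -> 600 nm conversion multiplies the weight by 5/6."""
        coeffs, comps = self._coeffs_and_comps(grid, dye)
        photon = self._photon(lam=500.0)
        xi_lam = float(dye.emission.cdf(600.0))  # deterministic: lands on 600 nm
        outcome, p = absorb_or_fluoresce(
            photon, coeffs, comps, 0.5, 0.0, 0.3, 0.7, xi_lam
        )
        assert outcome == "reemitted"
        assert p.lam == pytest.approx(600.0, abs=1e-3)  # table-inverted CDF
        assert p.weight == pytest.approx(500.0 / p.lam, rel=1e-12)
        assert p.weight == pytest.approx(5.0 / 6.0, rel=1e-5)
        assert p.n_cycles == 1

    def test_isotropic_reemission_mean_cosine_vanishes(self, grid, dye, rng):
        coeffs, comps = self._coeffs_and_comps(grid, dye)
        cosines = []
        for _ in range(4000):
            outcome, p = absorb_or_fluoresce(
                self._photon(), coeffs, comps, 0.5, 0.0,
                rng.random(), rng.random(), rng.random(),
            )
            cosines.append(p.direction[2])
        cosines = np.asarray(cosines)
        assert abs(cosines.mean()) < 3 / np.sqrt(3 * cosines.size)  # var = 1/3

    def test_base_component_absorbs_by_cumulative_fraction(self, grid, dye):
        coeffs, comps = self._coeffs_and_comps(grid, dye, base_mu_a=10.0)
        # base dominates mu_a at 500 nm: small xi0 lands in the base component
        outcome, name = absorb_or_fluoresce(
            self._photon(), coeffs, comps, 0.01, 0.5, 0.5, 0.5, 0.5
        )
        assert outcome == "terminated" and name == "solvent"


class TestLaunch:
    def test_delta_source_launches_in_its_only_bin(self, grid, rng):
        values = np.zeros(grid.n_bins)
        values[100] = 5.0
        src = Spectrum(grid, values)
        for xi in rng.random(20):
            p = launch_photon(src, "pencil", (xi,))
            assert grid.index_of(p.lam) == 100
            assert p.weight == 1.0
            np.testing.assert_allclose(p.direction, [0, 0, 1])

    def test_flat_two_bin_source_splits_evenly(self, grid, rng):
        values = np.zeros(grid.n_bins)
        values[[10, 11]] = 1.0
        src = Spectrum(grid, values)
        xis = rng.random(100_000)
        bins = np.array([grid.index_of(launch_photon(src, "pencil", (x,)).lam) for x in xis[:500]])
        assert set(bins) <= {10, 11}
        # analytic: bin 10 iff xi < 0.5; binomial check on the full draw
        frac = np.mean(xis < 0.5)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / xis.size)

    def test_zero_power_source_rejected(self, grid):
        with pytest.raises(ValueError):
            launch_photon(Spectrum(grid, np.zeros(grid.n_bins)), "pencil", (0.5,))
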