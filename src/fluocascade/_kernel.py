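"""Numba photon-transport kernel for the fluorescence cascade in layered slabs.

Analog event-based transport: exponential free paths from the total
extinction coefficient, absorption-vs-scattering decision at each
interaction, per-component selection by cumulative coefficient fractions,
Bernoulli re-emission against the quantum yield, isotropic re-emission with
inverse-CDF wavelength redistribution, unpolarized Fresnel boundaries.
Photon weights carry only the Stokes energy factor: an escaping photon's
weight is exactly lambda_launch / lambda_exit.

Randomness: a counter-based splitmix64 stream per photon, derived from
(seed, photon index), so results are independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLD = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_PHI2 = U64(0xD1B54A32D192ED03)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(state):
    state = state + _GOLD
    z = state
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    z = z ^ (z >> U64(31))
    return state, z


@njit(cache=True, inline="always")
def _u01(state):
    state, z = _splitmix64(state)
    return state, float(z >> U64(11)) * _INV53


@njit(cache=True, inline="always")
def _photon_stream(seed, index):
    state = (U64(seed) + U64(1)) * _GOLD ^ (U64(index) + U64(1)) * _PHI2
    state, _ = _splitmix64(state)
    state, _ = _splitmix64(state)
    return state


@njit(cache=True, inline="always")
def _bin_of(edges, lam):
    n = edges.shape[0] - 1
    b = np.searchsorted(edges, lam, side="right") - 1
    if b < 0:
        b = 0
    elif b > n - 1:
        b = n - 1
    return b


@njit(cache=True)
def hg_cos_theta(g, xi):
    """Henyey-Greenstein deflection cosine by analytic CDF inversion."""
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def rotate_direction(ux, uy, uz, cos_t, phi):
    """Rotate a unit vector by deflection cos_t and azimuth phi (MCML convention)."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cp
        ny = sin_t * sp
        nz = cos_t if uz > 0.0 else -cos_t
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cp - uy * sp) / tmp + ux * cos_t
        ny = sin_t * (uy * uz * cp + ux * sp) / tmp + uy * cos_t
        nz = -sin_t * cp * tmp + uz * cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def fresnel_unpolarized(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance and refracted cosine at a z-normal interface.

    Returns (R, cos_t); cos_t is 0 when totally internally reflected.
    """
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _icdf_lookup(table, xi):
    m = table.shape[0]
    pos = xi * (m - 1)
    i0 = int(pos)
    if i0 >= m - 1:
        i0 = m - 2
    frac = pos - i0
    return table[i0] * (1.0 - frac) + table[i0 + 1] * frac


@njit(cache=True)
def trace_photons(
    seed,
    n_photons,
    edges,  # (nbins+1,) wavelength bin edges, nm
    src_cdf,  # (nbins+1,) source CDF on edges (ignored if src_mode == 1)
    src_mode,  # 0: sample from src_cdf; 1: stratified, photon i -> bin i % nbins
    z_bounds,  # (L+1,) layer boundaries, mm
    n_stack,  # (L+2, nbins) refractive index: ambient above, layers, ambient below
    mua,  # (L, C, nbins) weighted absorption per component
    mus,  # (L, C, nbins) weighted scattering per component
    gg,  # (L, C, nbins) anisotropy per component
    comp_fluo,  # (C,) fluorophore slot index or -1
    phi_f,  # (F,)
    em_icdf,  # (F, M) inverse-CDF tables of the emission distributions
    fluor_on,  # 0/1: fluorescence branch enabled
    beam_mode,  # 0: collimated pencil along +z; 1: cosine-distributed incidence
    max_events,
):
    nbins = edges.shape[0] - 1
    n_layers = z_bounds.shape[0] - 1
    n_comp = mua.shape[1]

    refl_w = np.zeros(nbins)
    trans_w = np.zeros(nbins)
    launched_per_bin = np.zeros(nbins, np.int64)

    exit_side = np.zeros(n_photons, np.int8)  # 0 none, 1 reflectance, 2 transmission
    exit_x = np.zeros(n_photons)
    exit_y = np.zeros(n_photons)
    exit_ux = np.zeros(n_photons)
    exit_uy = np.zeros(n_photons)
    exit_uz = np.zeros(n_photons)
    exit_lam = np.zeros(n_photons)
    exit_w = np.zeros(n_photons)
    exit_ncyc = np.zeros(n_photons, np.int32)

    term_count = np.zeros((n_comp, 2), np.int64)  # [:, 0] primary, [:, 1] secondary
    term_weight = np.zeros((n_comp, 2))
    n_emission = 0
    n_fluo_abs = 0
    n_prim_fluo_abs = 0
    n_prim_any_abs = 0
    n_trapped = 0

    for i in range(n_photons):
        state = _photon_stream(seed, i)

        # launch wavelength
        if src_mode == 0:
            state, xi = _u01(state)
            lam = np.interp(xi, src_cdf, edges)
        else:
            b0 = i % nbins
            state, xi = _u01(state)
            lam = edges[b0] + xi * (edges[b0 + 1] - edges[b0])
        lam0 = lam
        b = _bin_of(edges, lam)
        launched_per_bin[b] += 1

        # launch direction
        if beam_mode == 0:
            ux = 0.0
            uy = 0.0
            uz = 1.0
        else:
            state, x1 = _u01(state)
            state, x2 = _u01(state)
            uz = np.sqrt(x1)
            sr = np.sqrt(max(0.0, 1.0 - uz * uz))
            ph = 2.0 * np.pi * x2
            ux = sr * np.cos(ph)
            uy = sr * np.sin(ph)

        x = 0.0
        y = 0.0
        z = 0.0
        layer = 0
        ncyc = 0

        # entry interface from the ambient above into layer 0
        n1 = n_stack[0, b]
        n2 = n_stack[1, b]
        R, cos_t = fresnel_unpolarized(n1, n2, uz)
        state, xi = _u01(state)
        if xi < R:
            refl_w[b] += 1.0
            exit_side[i] = 1
            exit_x[i] = x
            exit_y[i] = y
            exit_ux[i] = ux
            exit_uy[i] = uy
            exit_uz[i] = -uz
            exit_lam[i] = lam
            exit_w[i] = 1.0
            exit_ncyc[i] = 0
            continue
        scale = n1 / n2
        ux *= scale
        uy *= scale
        uz = cos_t

        events = 0
        side = 0  # 1 refl, 2 trans, 0 still inside
        while True:
            events += 1
            if events > max_events:
                n_trapped += 1
                side = -1
                break

            mua_tot = 0.0
            mus_tot = 0.0
            for c in range(n_comp):
                mua_tot += mua[layer, c, b]
                mus_tot += mus[layer, c, b]
            mut = mua_tot + mus_tot

            if mut > 0.0:
                state, xi = _u01(state)
                s = -np.log(1.0 - xi) / mut
            else:
                s = 1.0e30

            if uz > 0.0:
                db = (z_bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z - z_bounds[layer]) / (-uz)
            else:
                db = 1.0e30

            if s >= 1.0e29 and db >= 1.0e29:
                # horizontal photon in a vacuum layer: cannot ever interact
                n_trapped += 1
                side = -1
                break

            if db <= s:
                # boundary hit: move there, Fresnel decision
                x += ux * db
                y += uy * db
                going_down = uz > 0.0
                z = z_bounds[layer + 1] if going_down else z_bounds[layer]
                n1 = n_stack[layer + 1, b]
                n2 = n_stack[layer + 2, b] if going_down else n_stack[layer, b]
                R, cos_t = fresnel_unpolarized(n1, n2, abs(uz))
                state, xi = _u01(state)
                if xi < R:
                    uz = -uz
                else:
                    scale = n1 / n2
                    ux *= scale
                    uy *= scale
                    uz = cos_t if going_down else -cos_t
                    if going_down and layer == n_layers - 1:
                        side = 2
                        break
                    if (not going_down) and layer == 0:
                        side = 1
                        break
                    layer = layer + 1 if going_down else layer - 1
                continue

            # interaction inside the layer
            x += ux * s
            y += uy * s
            z += uz * s
            state, xi = _u01(state)
            if xi < mua_tot / mut:
                # absorption: pick the component by cumulative mu_a fractions
                state, xi0 = _u01(state)
                target = xi0 * mua_tot
                acc = 0.0
                csel = n_comp - 1
                for c in range(n_comp):
                    acc += mua[layer, c, b]
                    if target < acc:
                        csel = c
                        break
                primary = 0 if ncyc == 0 else 1
                if ncyc == 0:
                    n_prim_any_abs += 1
                f = comp_fluo[csel]
                if f >= 0 and fluor_on == 1:
                    n_fluo_abs += 1
                    if ncyc == 0:
                        n_prim_fluo_abs += 1
                    state, xi1 = _u01(state)
                    if xi1 > phi_f[f]:
                        term_count[csel, primary] += 1
                        term_weight[csel, primary] += lam0 / lam
                        side = 0
                        break
                    # re-emission: new wavelength, Stokes weight, isotropic direction
                    n_emission += 1
                    state, xil = _u01(state)
                    lam = _icdf_lookup(em_icdf[f], xil)
                    b = _bin_of(edges, lam)
                    ncyc += 1
                    state, x1 = _u01(state)
                    state, x2 = _u01(state)
                    cos_t = 1.0 - 2.0 * x1
                    sr = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                    ph = 2.0 * np.pi * x2
                    ux = sr * np.cos(ph)
                    uy = sr * np.sin(ph)
                    uz = cos_t
                else:
                    term_count[csel, primary] += 1
                    term_weight[csel, primary] += lam0 / lam
                    side = 0
                    break
            else:
                # scattering: pick the component by cumulative mu_s fractions
                state, xi0 = _u01(state)
                target = xi0 * mus_tot
                acc = 0.0
                csel = n_comp - 1
                for c in range(n_comp):
                    acc += mus[layer, c, b]
                    if target < acc:
                        csel = c
                        break
                gcur = gg[layer, csel, b]
                state, xt = _u01(state)
                state, xp = _u01(state)
                cos_t = hg_cos_theta(gcur, xt)
                ph = 2.0 * np.pi * xp
                ux, uy, uz = rotate_direction(ux, uy, uz, cos_t, ph)

        if side == 1 or side == 2:
            w = lam0 / lam  # telescoped product of the per-emission Stokes factors
            if side == 1:
                refl_w[b] += w
            else:
                trans_w[b] += w
            exit_side[i] = side
            exit_x[i] = x
            exit_y[i] = y
            exit_ux[i] = ux
            exit_uy[i] = uy
            exit_uz[i] = uz
            exit_lam[i] = lam
            exit_w[i] = w
            exit_ncyc[i] = ncyc

    return (
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
        n_prim_fluo_abs,
        n_prim_any_abs,
        n_trapped,
    )
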