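"""Levenberg-Marquardt retrieval of the quantum yield and emission distribution.

Nine free parameters — the quantum yield and the eight parameters of the
three-component emission mixture — are fitted by matching twin-simulated
reflectance and transmission spectra to measured ones, minimizing the RMSE
over the concatenated spectra.  Every objective evaluation reuses the same
random seed (common random numbers), making the stochastic forward model a
deterministic function of the parameters so that finite-difference LM
derivatives are meaningful.  Parameter transforms keep the iterates in the
physical region: logit for the yield, log for the widths, an interior
simplex map for the weights.

Because the transport is analog, the common-random-numbers objective is a
fine staircase in the parameters (each survival decision flips one photon
history at a time), so derivatives use fixed absolute steps on the
transformed scale, chosen large enough to average over many flipped
histories yet small against parameter curvature.  Statistical uncertainties
come from the residual-variance-scaled covariance of the LM Jacobian,
propagated to the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .emission import EmissionGMM
from .spectral import LayeredSample, Spectrum
from .sphere import InstrumentFunction, SphereGeometry, sample_diffuse_reflectance, simulate_detected_spectra

__all__ = ["FitResult", "objective_rmse", "fit"]

PARAM_NAMES = [
    "phi_f",
    "mu1_nm",
    "mu2_nm",
    "mu3_nm",
    "sigma1_nm",
    "sigma2_nm",
    "sigma3_nm",
    "w1",
    "w2",
]


@dataclass
class FitResult:
    phi_f: float
    gmm: EmissionGMM
    covariance: np.ndarray  # 9x9, natural scale
    stat_error: np.ndarray  # (9,)
    ci95: np.ndarray  # (9, 2)
    rmse: float
    n_iterations: int
    converged: bool
    param_names: tuple = tuple(PARAM_NAMES)

    @property
    def estimates(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.phi_f],
                self.gmm.means,
                self.gmm.sigmas,
                self.gmm.weights[:2],
            ]
        )

    def summary(self) -> str:
        lines = [f"{'parameter':<10} {'estimate':>10} {'stat_err':>10} {'ci95_lo':>10} {'ci95_hi':>10}"]
        for name, est, se, (lo, hi) in zip(
            self.param_names, self.estimates, self.stat_error, self.ci95
        ):
            lines.append(f"{name:<10} {est:>10.4f} {se:>10.4f} {lo:>10.4f} {hi:>10.4f}")
        lines.append(f"rmse = {self.rmse:.6g}  iterations = {self.n_iterations}  converged = {self.converged}")
        return "\n".join(lines)


def objective_rmse(
    simulated: tuple[Spectrum, Spectrum], measured: tuple[Spectrum, Spectrum]
) -> float:
    """Root-mean-square error over the concatenated R and T spectra."""
    res = _residuals(simulated, measured)
    return float(np.sqrt(np.mean(res**2)))


def _residuals(simulated, measured) -> np.ndarray:
    parts = []
    for sim, meas in zip(simulated, measured):
        if sim.grid != meas.grid:
            raise ValueError("simulated and measured spectra on different grids")
        parts.append(sim.values - meas.values)
    return np.concatenate(parts)


# -- parameter transforms ---------------------------------------------------


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return np.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _weights_to_free(w: np.ndarray) -> tuple[float, float]:
    w = np.clip(w, 1e-9, None)
    return float(np.log(w[0] / w[2])), float(np.log(w[1] / w[2]))


def _free_to_weights(y1: float, y2: float) -> np.ndarray:
    m = max(y1, y2, 0.0)
    e = np.exp(np.array([y1, y2, 0.0]) - m)
    return e / e.sum()


def _pack(phi_f: float, gmm: EmissionGMM) -> np.ndarray:
    y1, y2 = _weights_to_free(gmm.weights)
    return np.concatenate(
        [[_logit(phi_f)], gmm.means, np.log(gmm.sigmas), [y1, y2]]
    )


def _unpack(theta: np.ndarray, support) -> tuple[float, EmissionGMM]:
    phi_f = _expit(theta[0])
    w = _free_to_weights(theta[7], theta[8])
    gmm = EmissionGMM(theta[1:4].copy(), np.exp(theta[4:7]), w, support)
    return float(phi_f), gmm


def _natural_jacobian(theta: np.ndarray) -> np.ndarray:
    """d(natural params)/d(transformed params) at the solution (9x9)."""
    J = np.zeros((9, 9))
    p = _expit(theta[0])
    J[0, 0] = p * (1.0 - p)
    J[1:4, 1:4] = np.eye(3)
    J[4:7, 4:7] = np.diag(np.exp(theta[4:7]))
    w = _free_to_weights(theta[7], theta[8])
    # d w_i / d y_j for the softmax with the third logit pinned at 0
    for i in range(2):
        for j in range(2):
            J[7 + i, 7 + j] = w[i] * ((1.0 if i == j else 0.0) - w[j])
    return J


def fit(
    measured: tuple[Spectrum, Spectrum],
    sample: LayeredSample,
    source: Spectrum,
    geometry_r: SphereGeometry,
    geometry_t: SphereGeometry,
    init_gmm: EmissionGMM,
    init_phi_f: float,
    n_photons: int,
    seed: int,
    irf: InstrumentFunction | None = None,
    rho_sample: np.ndarray | None = None,
    fd_steps: np.ndarray | None = None,
    max_nfev: int | None = None,
    weighting: str = "none",
) -> FitResult:
    """LM fit of (phi_f, emission GMM) to measured (R, T) spectra.

    The sample's non-fluorescence optical properties are fixed inputs; only
    the single fluorescent component's yield and emission distribution vary.
    Bit-identical results for identical inputs and seed.

    ``weighting='inverse-variance'`` scales each residual by the reciprocal
    Monte Carlo shot-noise estimate (sigma ~ sqrt(measured value)), the GLS
    weighting for photon-count spectra; the default is the plain unweighted
    RMSE objective.  When an instrument function is part of the chain, the
    parameter covariance uses a sandwich estimator with the known
    kernel-induced residual correlation, so the reported uncertainties stay
    calibrated for smoothed spectra.
    """
    fluos = [
        c
        for layer in sample.layers
        for c, _ in layer.components
        if c.is_fluorescent
    ]
    fluos = list({id(c): c for c in fluos}.values())
    if len(fluos) != 1:
        raise ValueError("fit requires exactly one fluorescent component")
    dye = fluos[0]
    support = init_gmm.support

    # The sample-linked sphere reflectance is elastic (fluorescence off), so
    # it is parameter-independent: compute it once.
    if rho_sample is None:
        rho_sample = sample_diffuse_reflectance(
            sample, max(n_photons // 4, 10_000), (seed * 31 + 7) % 2**31
        )

    def forward(theta) -> tuple[Spectrum, Spectrum]:
        phi_f, gmm = _unpack(np.asarray(theta, float), support)
        new_dye = dye.with_fluorescence(phi_f, gmm)
        trial_layers = []
        for layer in sample.layers:
            comps = [
                (new_dye if c is dye else c, w) for c, w in layer.components
            ]
            trial_layers.append(
                type(layer)(layer.thickness_mm, layer.refractive_index, comps)
            )
        trial = LayeredSample(
            grid=sample.grid,
            layers=trial_layers,
            n_above=sample.n_above,
            n_below=sample.n_below,
        )
        return simulate_detected_spectra(
            trial,
            source,
            geometry_r,
            geometry_t,
            n_photons,
            seed,
            irf=irf,
            rho_sample=rho_sample,
        )

    if weighting == "inverse-variance":
        # shot-noise proxy: variance proportional to the measured level.
        # Weights come from a heavily smoothed copy of the measurement so
        # they are exogenous to the per-bin noise (weighting by the raw
        # noisy values biases the amplitude downward), floored to keep
        # empty bins from dominating.
        win = np.hanning(25)
        win /= win.sum()
        w_parts = []
        for meas in measured:
            smooth = np.convolve(meas.values, win, mode="same")
            floor = 0.02 * float(smooth.max())
            w_parts.append(1.0 / np.sqrt(np.maximum(smooth, floor)))
        res_weights = np.concatenate(w_parts)
        res_weights = res_weights / np.mean(res_weights)
    elif weighting == "none":
        res_weights = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def residuals(theta) -> np.ndarray:
        r = _residuals(forward(theta), measured)
        return r * res_weights if res_weights is not None else r

    if fd_steps is None:
        # absolute steps on the transformed scale: ~0.02 in phi_f, 0.5 nm in
        # the means, ~2% in the widths, ~0.05 in the weight logits
        fd_steps = np.array([0.12, 0.5, 0.5, 0.5, 0.02, 0.02, 0.02, 0.05, 0.05])
    fd_steps = np.asarray(fd_steps, dtype=float)

    def jacobian(theta) -> np.ndarray:
        r0 = residuals(theta)
        J = np.empty((r0.size, theta.size))
        for j in range(theta.size):
            tp = np.array(theta, dtype=float)
            tp[j] += fd_steps[j]
            J[:, j] = (residuals(tp) - r0) / fd_steps[j]
        return J

    theta0 = _pack(init_phi_f, init_gmm)
    res = optimize.least_squares(
        residuals,
        theta0,
        jac=jacobian,
        method="lm",
        x_scale="jac",
        max_nfev=max_nfev,
    )

    # Heteroscedasticity-consistent sandwich covariance: the residual noise
    # mixes Monte Carlo shot noise and multiplicative detector noise, whose
    # per-bin variances differ by orders of magnitude across the spectrum,
    # and the instrument kernel correlates neighbouring bins.  Estimate the
    # local residual variance by a moving average of squared residuals and
    # build Sigma = sqrt(d) C sqrt(d) with C the kernel autocorrelation.
    m, p = res.fun.size, theta0.size
    if irf is not None and irf.kernel.size > 1:
        c = np.correlate(irf.kernel, irf.kernel, mode="full")
        c = c / c.max()
    else:
        c = np.array([1.0])
    # effective dof: with kernel-correlated noise the fit absorbs about
    # p * l_eff correlated degrees of freedom (l_eff = correlation length)
    l_eff = float(c.sum())
    dof_factor = m / max(m - p * l_eff, 1.0)
    n_seg = measured[0].grid.n_bins
    win = np.ones(31) / 31.0
    d = np.empty(m)
    for a, b in ((0, n_seg), (n_seg, m)):
        seg = res.fun[a:b] ** 2
        d[a:b] = np.convolve(seg, win, mode="same")
    d = dof_factor * np.maximum(d, 1e-30)
    sqrt_d = np.sqrt(d)
    sigma_J = np.empty_like(res.jac)
    for j in range(p):
        col = sqrt_d * res.jac[:, j]
        sigma_J[:n_seg, j] = np.convolve(col[:n_seg], c, mode="same")
        sigma_J[n_seg:, j] = np.convolve(col[n_seg:], c, mode="same")
        sigma_J[:, j] *= sqrt_d
    JtJ = res.jac.T @ res.jac
    JtJ_inv = np.linalg.pinv(JtJ)
    cov_t = JtJ_inv @ (res.jac.T @ sigma_J) @ JtJ_inv
    Jn = _natural_jacobian(res.x)
    cov_nat = Jn @ cov_t @ Jn.T
    cov_nat = 0.5 * (cov_nat + cov_nat.T)  # symmetrize against roundoff
    stat_error = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))

    phi_f, gmm = _unpack(res.x, support)
    estimates = np.concatenate([[phi_f], gmm.means, gmm.sigmas, gmm.weights[:2]])
    ci95 = np.column_stack(
        [estimates - 1.96 * stat_error, estimates + 1.96 * stat_error]
    )
    final = res.fun / res_weights if res_weights is not None else res.fun
    rmse = float(np.sqrt(np.mean(final**2)))
    return FitResult(
        phi_f=phi_f,
        gmm=gmm,
        covariance=cov_nat,
        stat_error=stat_error,
        ci95=ci95,
        rmse=rmse,
        n_iterations=int(res.nfev),
        converged=bool(res.success),
    )
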