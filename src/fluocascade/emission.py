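"""Intrinsic emission distribution: truncated 3-component Gaussian mixture.

The intrinsic emission probability density P̃f(λ) of a fluorophore is modelled
as a mixture of three Gaussians with two free weights (the third is fixed by
normalization), truncated to a finite support and renormalized so that the
density integrates to one there.  Eight parameters are free: three means,
three standard deviations, two weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr  # standard normal CDF, vectorized

from .spectral import Spectrum

__all__ = ["EmissionGMM", "sample_wavelength", "init_from_spectrum"]

_SQRT2PI = np.sqrt(2.0 * np.pi)
_ICDF_POINTS = 4097  # resolution of the cached inverse-CDF table


@dataclass
class EmissionGMM:
    """Three-component Gaussian mixture on a truncated wavelength support.

    Components are kept sorted by mean so that fits are comparable up to
    label switching.
    """

    means: np.ndarray  # nm
    sigmas: np.ndarray  # nm
    weights: np.ndarray  # sums to 1
    support: tuple[float, float]
    _icdf_table: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if m.shape != (3,) or s.shape != (3,) or w.shape != (3,):
            raise ValueError("means, sigmas and weights must each have 3 entries")
        if np.any(s <= 0):
            raise ValueError("sigmas must be > 0")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        order = np.argsort(m)
        self.means, self.sigmas, self.weights = m[order], s[order], w[order]
        lo, hi = float(self.support[0]), float(self.support[1])
        if not lo < hi:
            raise ValueError("support must satisfy lambda_min < lambda_max")
        self.support = (lo, hi)
        self._icdf_table = None

    @classmethod
    def from_free_weights(
        cls, means, sigmas, w1: float, w2: float, support
    ) -> "EmissionGMM":
        """Construct from the 8 free parameters; w3 = 1 - w1 - w2."""
        if w1 < 0 or w2 < 0 or w1 + w2 > 1 + 1e-12:
            raise ValueError("need w1, w2 >= 0 and w1 + w2 <= 1")
        return cls(
            np.asarray(means, float),
            np.asarray(sigmas, float),
            np.array([w1, w2, 1.0 - w1 - w2]),
            tuple(support),
        )

    # -- density -----------------------------------------------------------

    def _truncation_mass(self) -> float:
        lo, hi = self.support
        mass = np.sum(
            self.weights
            * (ndtr((hi - self.means) / self.sigmas) - ndtr((lo - self.means) / self.sigmas))
        )
        if mass <= 0:
            raise ValueError("mixture has no mass on the support")
        return float(mass)

    def pdf(self, lam) -> np.ndarray:
        """Truncated-renormalized density per nm; zero outside the support."""
        lam = np.asarray(lam, dtype=float)
        z = (lam[..., None] - self.means) / self.sigmas
        raw = np.sum(
            self.weights / (self.sigmas * _SQRT2PI) * np.exp(-0.5 * z * z), axis=-1
        )
        lo, hi = self.support
        out = np.where((lam >= lo) & (lam <= hi), raw / self._truncation_mass(), 0.0)
        return out if out.shape else float(out)

    def cdf(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        lo, hi = self.support
        lam_c = np.clip(lam, lo, hi)
        up = np.sum(self.weights * ndtr((lam_c[..., None] - self.means) / self.sigmas), axis=-1)
        at_lo = np.sum(self.weights * ndtr((lo - self.means) / self.sigmas))
        out = (up - at_lo) / self._truncation_mass()
        out = np.clip(out, 0.0, 1.0)
        return out if out.shape else float(out)

    # -- sampling ----------------------------------------------------------

    def icdf_table(self, n_points: int = _ICDF_POINTS) -> np.ndarray:
        """Wavelengths at n_points equispaced quantiles in [0, 1] (cached)."""
        if self._icdf_table is not None and self._icdf_table.size == n_points:
            return self._icdf_table
        lo, hi = self.support
        # Dense grid fine enough that linear interpolation of the CDF is
        # far below sampling noise at 1e6 draws.
        lam = np.linspace(lo, hi, 16 * n_points)
        c = np.asarray(self.cdf(lam))
        c[0], c[-1] = 0.0, 1.0
        c = np.maximum.accumulate(c)
        q = np.linspace(0.0, 1.0, n_points)
        table = np.interp(q, c, lam)
        self._icdf_table = table
        return table

    def ppf(self, q) -> np.ndarray:
        """Inverse CDF by interpolation of the cached quantile table."""
        q = np.asarray(q, dtype=float)
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("quantiles must lie in [0, 1]")
        table = self.icdf_table()
        out = np.interp(q * (table.size - 1), np.arange(table.size), table)
        return out if out.shape else float(out)

    def sample(self, xi) -> np.ndarray:
        """Inverse-CDF sample(s): deterministic function of uniform deviates."""
        return self.ppf(xi)

    def mean(self) -> float:
        lo, hi = self.support
        lam = np.linspace(lo, hi, 8192)
        p = np.asarray(self.pdf(lam))
        return float(np.trapezoid(lam * p, lam))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "means_nm": [float(v) for v in self.means],
            "sigmas_nm": [float(v) for v in self.sigmas],
            "weights": [float(v) for v in self.weights],
            "support_nm": [float(self.support[0]), float(self.support[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmissionGMM":
        return cls(
            np.asarray(d["means_nm"], float),
            np.asarray(d["sigmas_nm"], float),
            np.asarray(d["weights"], float),
            tuple(d["support_nm"]),
        )


def sample_wavelength(model: EmissionGMM, xi: float) -> float:
    """Draw an emission wavelength from P̃f by inverse-CDF transform."""
    return float(model.ppf(xi))


def _weights_from_free(y1: float, y2: float) -> np.ndarray:
    """Softmax map from two unconstrained parameters to the weight simplex."""
    e = np.exp(np.array([y1, y2, 0.0]) - max(y1, y2, 0.0))
    return e / e.sum()


def init_from_spectrum(
    measured_emission: Spectrum,
    support: tuple[float, float] | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> EmissionGMM:
    """Least-squares GMM fit to an area-normalized emission spectrum.

    Used to initialize the intrinsic emission distribution from a measured
    fluorescence spectrum (a proxy distorted by re-absorption, later refined
    by the full inversion).  Multi-start nonlinear least squares guards
    against local minima.
    """
    grid = measured_emission.grid
    y = np.asarray(measured_emission.values, dtype=float)
    if np.all(y == 0):
        raise ValueError("cannot fit an all-zero spectrum")
    if np.any(y < 0):
        raise ValueError("emission spectrum must be non-negative")
    lam = grid.centers
    widths = grid.widths
    y_pdf = y / np.sum(y * widths)  # area-normalized density per nm
    if support is None:
        support = (grid.lo, grid.hi)

    peak = float(lam[np.argmax(y_pdf)])
    total = np.sum(y_pdf * widths)
    sigma_hat = float(
        np.sqrt(max(np.sum((lam - peak) ** 2 * y_pdf * widths) / total, 1.0))
    )

    rng = np.random.default_rng(seed)
    starts = []
    for k in range(n_starts):
        if k == 0:
            mu0 = peak + sigma_hat * np.array([-0.5, 0.0, 1.0])
            sg0 = sigma_hat * np.array([0.6, 0.8, 1.2])
        elif k == 1:
            mu0 = peak + sigma_hat * np.array([-1.0, 0.5, 2.0])
            sg0 = sigma_hat * np.array([0.5, 1.0, 1.5])
        else:
            mu0 = peak + sigma_hat * rng.uniform(-1.5, 2.5, size=3)
            sg0 = sigma_hat * rng.uniform(0.4, 1.6, size=3)
        starts.append((np.sort(mu0), sg0))

    lo, hi = support
    bounds_lo = np.concatenate([[lo] * 3, [0.3] * 3, [-20.0] * 2])
    bounds_hi = np.concatenate([[hi] * 3, [(hi - lo)] * 3, [20.0] * 2])

    def residuals(theta):
        model = EmissionGMM.from_free_weights(
            theta[0:3],
            theta[3:6],
            *(_weights_from_free(theta[6], theta[7])[:2]),
            support,
        )
        return np.asarray(model.pdf(lam)) - y_pdf

    best = None
    for mu0, sg0 in starts:
        theta0 = np.concatenate([mu0, np.clip(sg0, 0.4, hi - lo), [0.0, 0.0]])
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(bounds_lo, bounds_hi), xtol=1e-12, ftol=1e-12
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("GMM initialization failed from every start")

    theta = best.x
    w = _weights_from_free(theta[6], theta[7])
    model = EmissionGMM(theta[0:3], theta[3:6], w, support)
    model.fit_residual = float(np.sqrt(2 * best.cost / lam.size))  # type: ignore[attr-defined]
    return model
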