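"""Spectral data model: wavelength grid, component optical properties, layered samples.

Units are fixed throughout the package: wavelengths in nm, lengths in mm,
absorption/scattering coefficients in mm^-1.  All wavelength-resolved
quantities live on a shared :class:`SpectralGrid` of half-open bins
``[lambda_k, lambda_k+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .emission import EmissionGMM

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "ComponentOpticalProperties",
    "Layer",
    "LayeredSample",
    "MixtureCoefficients",
    "load_spectra_table",
    "write_spectra_table",
]


@dataclass(frozen=True, eq=False)
class SpectralGrid:
    """Half-open wavelength bins ``[edges[k], edges[k+1])`` in nm."""

    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        object.__setattr__(self, "bin_edges", edges)

    @classmethod
    def default(cls, lo: float = 350.0, hi: float = 800.0, step: float = 1.0) -> "SpectralGrid":
        n = int(round((hi - lo) / step))
        return cls(lo + step * np.arange(n + 1))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def lo(self) -> float:
        return float(self.bin_edges[0])

    @property
    def hi(self) -> float:
        return float(self.bin_edges[-1])

    def index_of(self, lam) -> np.ndarray:
        """Bin index of wavelength(s), honouring the half-open convention."""
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.lo) or np.any(lam >= self.hi):
            raise ValueError(
                f"wavelength outside grid [{self.lo}, {self.hi}) nm"
            )
        return np.minimum(
            np.searchsorted(self.bin_edges, lam, side="right") - 1, self.n_bins - 1
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.bin_edges, other.bin_edges
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpectralGrid({self.lo:g}..{self.hi:g} nm, {self.n_bins} bins)"
        )


@dataclass
class Spectrum:
    """Radiant power (or dimensionless weight) per wavelength bin."""

    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values shape {v.shape} does not match grid ({self.grid.n_bins} bins)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        self.values = v

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean_wavelength(self) -> float:
        t = self.total
        if t <= 0:
            raise ValueError("mean wavelength of an empty spectrum")
        return float(np.dot(self.grid.centers, self.values) / t)

    def normalized(self) -> "Spectrum":
        t = self.total
        if t <= 0:
            raise ValueError("cannot normalize a zero spectrum")
        return Spectrum(self.grid, self.values / t)

    def cdf_on_edges(self) -> np.ndarray:
        """Cumulative distribution on bin edges (piecewise-linear within bins)."""
        t = self.values.sum()
        if t <= 0:
            raise ValueError("cannot build a CDF from a zero spectrum")
        return np.concatenate([[0.0], np.cumsum(self.values)]) / t

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if self.grid != other.grid:
            raise ValueError("grid mismatch")
        return Spectrum(self.grid, self.values + other.values)


@dataclass
class ComponentOpticalProperties:
    """One material component's wavelength-resolved optical properties.

    ``mu_a``/``mu_s`` are per-mm coefficients at the reference concentration
    (weight 1); ``g`` is the Henyey-Greenstein anisotropy.  Fluorescent
    components additionally carry a quantum yield ``phi_f`` and an intrinsic
    emission distribution (3-component Gaussian mixture).
    """

    name: str
    grid: SpectralGrid
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    is_fluorescent: bool = False
    phi_f: float | None = None
    emission: "EmissionGMM | None" = None

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        for attr in ("mu_a", "mu_s", "g"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape == ():
                v = np.full(n, float(v))
            if v.shape != (n,):
                raise ValueError(f"{attr} must have one value per grid bin")
            setattr(self, attr, v)
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ValueError(f"component {self.name!r}: negative coefficients")
        if np.any(np.abs(self.g) >= 1):
            raise ValueError(f"component {self.name!r}: |g| must be < 1")
        if self.is_fluorescent:
            if self.phi_f is None or not (0.0 <= self.phi_f <= 1.0):
                raise ValueError(
                    f"fluorescent component {self.name!r} needs phi_f in [0, 1]"
                )
            if self.emission is None:
                raise ValueError(
                    f"fluorescent component {self.name!r} needs an emission model"
                )
        else:
            if self.phi_f is not None or self.emission is not None:
                raise ValueError(
                    f"non-fluorescent component {self.name!r} must not carry an emission model"
                )

    def with_fluorescence(self, phi_f: float, emission: "EmissionGMM") -> "ComponentOpticalProperties":
        """Copy of this component with a (new) quantum yield and emission model."""
        return ComponentOpticalProperties(
            name=self.name,
            grid=self.grid,
            mu_a=self.mu_a,
            mu_s=self.mu_s,
            g=self.g,
            is_fluorescent=True,
            phi_f=float(phi_f),
            emission=emission,
        )


@dataclass
class Layer:
    """One slab layer: thickness, refractive index, weighted component mix."""

    thickness_mm: float
    refractive_index: float | np.ndarray
    components: Sequence[tuple[ComponentOpticalProperties, float]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be > 0")
        for comp, w in self.components:
            if w < 0:
                raise ValueError(f"component weight for {comp.name!r} must be >= 0")

    def index_on(self, grid: SpectralGrid) -> np.ndarray:
        n = np.asarray(self.refractive_index, dtype=float)
        if n.shape == ():
            n = np.full(grid.n_bins, float(n))
        if n.shape != (grid.n_bins,):
            raise ValueError("refractive index array does not match grid")
        if np.any(n <= 0):
            raise ValueError("refractive index must be > 0")
        return n


class MixtureCoefficients(NamedTuple):
    """Concentration-weighted coefficients of one layer at one wavelength."""

    mu_a_base: float
    mu_a_fluo: np.ndarray  # per fluorescent component, layer order
    mu_s: np.ndarray  # per component (all), layer order

    @property
    def mu_a_total(self) -> float:
        return float(self.mu_a_base + self.mu_a_fluo.sum())

    @property
    def mu_s_total(self) -> float:
        return float(self.mu_s.sum())


@dataclass
class LayeredSample:
    """Slab stack, top (illuminated, z=0) to bottom, with ambient indices."""

    grid: SpectralGrid
    layers: Sequence[Layer]
    n_above: float | np.ndarray = 1.0
    n_below: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("a sample needs at least one layer")
        for layer in self.layers:
            layer.index_on(self.grid)  # validates
            for comp, _ in layer.components:
                if comp.grid != self.grid:
                    raise ValueError(
                        f"component {comp.name!r} is resolved on a different grid"
                    )

    @property
    def total_thickness_mm(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    @property
    def z_bounds(self) -> np.ndarray:
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness_mm for l in self.layers])]
        )

    def ambient_index_on(self, which: str) -> np.ndarray:
        n = np.asarray(
            self.n_above if which == "above" else self.n_below, dtype=float
        )
        if n.shape == ():
            n = np.full(self.grid.n_bins, float(n))
        return n

    def mixture_coefficients(self, layer_index: int, lam: float) -> MixtureCoefficients:
        """Weighted per-component coefficients of one layer at wavelength ``lam``.

        Total absorption is ``mu_a_base + sum(mu_a_fluo)``, the additive
        mixture used by the interaction algorithm.
        """
        if not (0 <= layer_index < len(self.layers)):
            raise IndexError(f"no layer {layer_index}")
        b = int(self.grid.index_of(lam))
        layer = self.layers[layer_index]
        mu_a_base = 0.0
        mu_a_fluo = []
        mu_s = []
        for comp, w in layer.components:
            mu_s.append(w * comp.mu_s[b])
            if comp.is_fluorescent:
                mu_a_fluo.append(w * comp.mu_a[b])
            else:
                mu_a_base += w * comp.mu_a[b]
        return MixtureCoefficients(
            mu_a_base=float(mu_a_base),
            mu_a_fluo=np.asarray(mu_a_fluo, dtype=float),
            mu_s=np.asarray(mu_s, dtype=float),
        )


_REQUIRED_COLUMNS = ("wavelength_nm", "mu_a_per_mm", "mu_s_per_mm", "g")


def load_spectra_table(
    path,
    grid: SpectralGrid,
    name: str | None = None,
) -> ComponentOpticalProperties:
    """Read a delimited spectra table and interpolate onto the grid centers.

    The table must carry a header naming at least the columns
    ``wavelength_nm, mu_a_per_mm, mu_s_per_mm, g``.  Values are linearly
    interpolated onto the grid bin centers; wavelengths outside the table's
    range raise (no extrapolation).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(lam) > 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")
    centers = grid.centers
    if centers[0] < lam[0] or centers[-1] > lam[-1]:
        raise ValueError(
            f"{path}: table covers {lam[0]:g}-{lam[-1]:g} nm but the grid "
            f"needs {centers[0]:g}-{centers[-1]:g} nm (no extrapolation)"
        )
    cols = {}
    for col in ("mu_a_per_mm", "mu_s_per_mm", "g"):
        v = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            raise ValueError(f"{path}: non-finite values in column {col!r}")
        cols[col] = np.interp(centers, lam, v)
    if np.any(cols["mu_a_per_mm"] < 0) or np.any(cols["mu_s_per_mm"] < 0):
        raise ValueError(f"{path}: negative coefficients")
    return ComponentOpticalProperties(
        name=name if name is not None else str(path),
        grid=grid,
        mu_a=cols["mu_a_per_mm"],
        mu_s=cols["mu_s_per_mm"],
        g=cols["g"],
    )


def write_spectra_table(comp: ComponentOpticalProperties, path) -> None:
    """Write a component's property table at the grid centers (round-trip safe)."""
    df = pd.DataFrame(
        {
            "wavelength_nm": comp.grid.centers,
            "mu_a_per_mm": comp.mu_a,
            "mu_s_per_mm": comp.mu_s,
            "g": comp.g,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
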