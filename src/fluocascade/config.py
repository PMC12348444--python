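"""Structured (YAML) scene configuration: grid, components, layers, sphere.

A scene file references component spectra tables (CSV/TSV with the standard
header), describes the layer stack with per-layer component weights, the
surrounding refractive indices, an optional source table, and the sphere
geometry blocks.  ``load_scene`` resolves everything onto the grid and
validates all invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emission import EmissionGMM
from .spectral import (
    ComponentOpticalProperties,
    Layer,
    LayeredSample,
    SpectralGrid,
    Spectrum,
    load_spectra_table,
)
from .sphere import SphereGeometry, SphereSurface

__all__ = ["Scene", "load_scene", "load_spectrum_table"]


@dataclass
class Scene:
    grid: SpectralGrid
    components: dict[str, ComponentOpticalProperties]
    sample: LayeredSample
    source: Spectrum | None = None
    geometry_r: SphereGeometry | None = None
    geometry_t: SphereGeometry | None = None
    meta: dict = field(default_factory=dict)


def load_spectrum_table(path, grid: SpectralGrid) -> Spectrum:
    """Two-column (wavelength_nm, power) table interpolated onto the grid."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "wavelength_nm" not in df.columns or "power" not in df.columns:
        raise ValueError(f"{path}: spectrum table needs wavelength_nm and power columns")
    lam = df["wavelength_nm"].to_numpy(float)
    if not np.all(np.diff(lam) > 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")
    values = np.interp(grid.centers, lam, df["power"].to_numpy(float), left=0.0, right=0.0)
    return Spectrum(grid, np.maximum(values, 0.0))


def _build_geometry(block: dict) -> SphereGeometry:
    surfaces = []
    for s in block.get("surfaces", []):
        surfaces.append(
            SphereSurface(
                label=s["label"],
                area_mm2=float(s["area_mm2"]),
                reflectance=None if s.get("reflectance") == "sample" else float(s.get("reflectance", 0.0)),
                direction=np.asarray(s["direction"], float),
                kind=s.get("kind", "port"),
            )
        )
    return SphereGeometry(
        diameter_mm=float(block.get("diameter_mm", 150.0)),
        wall_reflectance=float(block.get("wall_reflectance", 0.95)),
        detector_area_mm2=float(block.get("detector_area_mm2", 78.5)),
        fov_area_mm2=float(block.get("fov_area_mm2", 700.0)),
        fov_direction=np.asarray(block.get("fov_direction", [0.0, 0.5, 0.866]), float),
        surfaces=surfaces,
    )


def load_scene(path) -> Scene:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent

    gb = cfg.get("grid", {})
    grid = SpectralGrid.default(
        float(gb.get("min_nm", 350.0)),
        float(gb.get("max_nm", 800.0)),
        float(gb.get("step_nm", 1.0)),
    )

    components: dict[str, ComponentOpticalProperties] = {}
    for name, block in cfg.get("components", {}).items():
        comp = load_spectra_table(base / block["table"], grid, name=name)
        if "phi_f" in block:
            emission = EmissionGMM.from_dict(block["emission"])
            comp = comp.with_fluorescence(float(block["phi_f"]), emission)
        components[name] = comp

    layers = []
    for lb in cfg["layers"]:
        comps = [(components[n], float(w)) for n, w in lb.get("components", {}).items()]
        layers.append(
            Layer(
                thickness_mm=float(lb["thickness_mm"]),
                refractive_index=float(lb["refractive_index"]),
                components=comps,
            )
        )
    amb = cfg.get("ambient", {})
    sample = LayeredSample(
        grid=grid,
        layers=layers,
        n_above=float(amb.get("above", 1.0)),
        n_below=float(amb.get("below", 1.0)),
    )

    source = None
    if "source" in cfg:
        source = load_spectrum_table(base / cfg["source"]["table"], grid)

    geometry_r = _build_geometry(cfg["sphere_reflectance"]) if "sphere_reflectance" in cfg else None
    geometry_t = _build_geometry(cfg["sphere_transmission"]) if "sphere_transmission" in cfg else None

    return Scene(
        grid=grid,
        components=components,
        sample=sample,
        source=source,
        geometry_r=geometry_r,
        geometry_t=geometry_t,
        meta=cfg.get("meta", {}),
    )
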