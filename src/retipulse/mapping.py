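"""Spatial amplitude maps, heat-map export, and ophthalmodynamometry units.

A cluster grid of harmonic fits becomes an :class:`AmplitudeMap`: one value
(HRW_a, a Fourier coefficient, or the intercept) per pixel cluster.  Maps
are exported as false-color PNGs; the value-to-color normalization can be
shared across all force levels of one eye so that amplitude growth with
ophthalmodynamometric force is visible across panels.

Force units: the Meditron ophthalmodynamometer displays Meditron units (mu);
1 mu = 3.33 grams force, and the induced intraocular pressure is
0.89 * ODF(g) + baseline IOP (mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "AmplitudeMap",
    "ODFMeasurement",
    "mu_to_grams",
    "induced_iop",
    "build_amplitude_map",
    "export_heatmap",
    "GRAMS_PER_MU",
    "IOP_PER_GRAM",
]

GRAMS_PER_MU = 3.33
IOP_PER_GRAM = 0.89

_VALUE_KINDS = ("hrw_a", "a1", "b1", "a2", "b2", "intercept")


def mu_to_grams(mu):
    """Convert Meditron units to grams of force (1 mu = 3.33 g)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DomainError("Meditron units must be >= 0")
    g = GRAMS_PER_MU * mu
    return g if g.ndim else float(g)


def induced_iop(odf_g, baseline_iop_mmhg, baseline_bounds=(5.0, 60.0)):
    """Induced intraocular pressure: 0.89 * ODF + baseline (mmHg)."""
    odf_g = np.asarray(odf_g, dtype=float)
    if np.any(odf_g < 0):
        raise DomainError("ODF must be >= 0")
    lo, hi = baseline_bounds
    if not lo <= baseline_iop_mmhg <= hi:
        raise DomainError(
            f"baseline IOP {baseline_iop_mmhg} outside physiologic "
            f"bounds [{lo}, {hi}] mmHg"
        )
    iop = IOP_PER_GRAM * odf_g + baseline_iop_mmhg
    return iop if iop.ndim else float(iop)


@dataclass
class ODFMeasurement:
    """One ophthalmodynamometric force reading with derived quantities."""

    mu: float
    baseline_iop_mmhg: float
    grams: float = field(init=False)
    induced_iop_mmhg: float = field(init=False)

    def __post_init__(self):
        self.grams = mu_to_grams(self.mu)
        self.induced_iop_mmhg = induced_iop(self.grams, self.baseline_iop_mmhg)


@dataclass
class AmplitudeMap:
    """Grid of per-cluster fitted values."""

    grid: np.ndarray  # (rows, cols), NaN where missing
    cluster_size: int
    value_kind: str = "hrw_a"
    origin: tuple = (0, 0)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2:
            raise ConfigurationError("grid must be 2-D")
        if self.value_kind not in _VALUE_KINDS:
            raise ConfigurationError(
                f"value_kind must be one of {_VALUE_KINDS}"
            )
        if self.value_kind == "hrw_a" and np.nanmin(grid, initial=0.0) < 0:
            raise ConfigurationError("hrw_a map values must be >= 0")
        self.grid = grid

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.grid)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


def build_amplitude_map(fit_grid, value_kind: str = "hrw_a",
                        cluster_size: int | None = None,
                        origin=(0, 0)) -> AmplitudeMap:
    """Assemble an :class:`AmplitudeMap` from a 2-D grid of harmonic fits.

    ``fit_grid`` is a nested sequence (rows x cols) of
    :class:`~retipulse.harmonic.HarmonicFit` or None (missing cluster).
    All fits must carry the same cluster size in their metadata if
    ``cluster_size`` is not given.
    """
    rows = len(fit_grid)
    cols = len(fit_grid[0]) if rows else 0
    grid = np.full((rows, cols), np.nan)
    sizes = set()
    for r in range(rows):
        for c in range(cols):
            f = fit_grid[r][c]
            if f is None:
                continue
            if "cluster_size" in f.metadata:
                sizes.add(f.metadata["cluster_size"])
            if value_kind == "hrw_a":
                grid[r, c] = f.hrw_a
            elif value_kind == "intercept":
                grid[r, c] = f.intercept
            else:
                idx = int(value_kind[1]) - 1
                arr = f.a if value_kind[0] == "a" else f.b
                grid[r, c] = arr[idx]
    if cluster_size is None:
        if len(sizes) > 1:
            raise ConfigurationError(f"mixed cluster sizes in fits: {sizes}")
        cluster_size = sizes.pop() if sizes else 1
    elif sizes and sizes != {cluster_size}:
        raise ConfigurationError(f"mixed cluster sizes in fits: {sizes}")
    return AmplitudeMap(grid=grid, cluster_size=int(cluster_size),
                        value_kind=value_kind, origin=tuple(origin))


def export_heatmap(amap: AmplitudeMap, path, vmin=None, vmax=None,
                   cmap: str = "viridis", missing_gray: int = 128):
    """Write a false-color PNG of the map.

    ``vmin``/``vmax`` fix the value-to-color scale; pass the shared range of
    all force levels of one eye to make panels comparable.  Missing cells
    render neutral gray.  Returns metadata about the export (colormap name
    and scale), which is also what makes re-exports byte-reproducible.
    """
    import matplotlib
    from PIL import Image

    if amap.grid.size == 0 or np.all(amap.missing):
        raise ConfigurationError("cannot export an empty map")
    finite = amap.grid[~amap.missing]
    lo = float(np.min(finite) if vmin is None else vmin)
    hi = float(np.max(finite) if vmax is None else vmax)
    span = hi - lo if hi > lo else 1.0
    normed = np.clip((amap.grid - lo) / span, 0.0, 1.0)
    colormap = matplotlib.colormaps[cmap]
    rgba = colormap(np.nan_to_num(normed))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[amap.missing] = missing_gray
    Image.fromarray(rgb).save(path)
    return {"path": str(path), "cmap": cmap, "vmin": lo, "vmax": hi,
            "missing_gray": missing_gray}
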