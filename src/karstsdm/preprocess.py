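"""Raster alignment, standardization and terrain derivatives.

Terrain variables follow the conventions of mainstream raster GIS engines:
slope/aspect by Horn's 8-neighbour weighted differences, TRI as the mean
absolute elevation difference to the 8 neighbours, and TPI as the cell value
minus the mean over a circular neighbourhood of a given radius in metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve

from .grids import CATEGORICAL, CONTINUOUS, Grid, RasterLayer, RasterStack


class DegeneratePredictorError(ValueError):
    """A predictor has zero variance over the reference cells."""


# ---------------------------------------------------------------------------
# Alignment / resampling


def _fractional_index(target: Grid, source: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Fractional (row, col) position of target cell centres in source index space."""
    rows, cols = np.mgrid[0 : target.n_rows, 0 : target.n_cols]
    x, y = target.cell_center(rows, cols)
    fc = (x - source.origin_x) / source.cell_size - 0.5
    fr = (source.origin_y - y) / source.cell_size - 0.5
    return fr, fc


def _resample_bilinear(layer: RasterLayer, target: Grid) -> np.ndarray:
    src = layer.values
    fr, fc = _fractional_index(target, layer.grid)
    out = np.full(target.shape, np.nan)
    nr, nc = layer.grid.shape
    inb = (fr >= 0) & (fr <= nr - 1) & (fc >= 0) & (fc <= nc - 1)
    fr_i, fc_i = fr[inb], fc[inb]
    r0 = np.clip(np.floor(fr_i).astype(int), 0, nr - 1)
    c0 = np.clip(np.floor(fc_i).astype(int), 0, nc - 1)
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)
    wr = fr_i - r0
    wc = fc_i - c0
    corners = (
        (src[r0, c0], (1 - wr) * (1 - wc)),
        (src[r0, c1], (1 - wr) * wc),
        (src[r1, c0], wr * (1 - wc)),
        (src[r1, c1], wr * wc),
    )
    acc = np.zeros_like(wr)
    bad = np.zeros_like(wr, dtype=bool)
    for v, w in corners:
        contributes = w > 1e-12
        bad |= contributes & ~np.isfinite(v)
        acc += np.where(contributes, np.nan_to_num(v) * w, 0.0)
    acc[bad] = np.nan
    out[inb] = acc
    return out


def _resample_nearest(layer: RasterLayer, target: Grid) -> np.ndarray:
    src = layer.values
    fr, fc = _fractional_index(target, layer.grid)
    out = np.full(target.shape, np.nan)
    nr, nc = layer.grid.shape
    r = np.round(fr).astype(int)
    c = np.round(fc).astype(int)
    inb = (r >= 0) & (r < nr) & (c >= 0) & (c < nc)
    out[inb] = src[r[inb], c[inb]]
    return out


def align_stack(layers: Sequence[RasterLayer], target: Grid) -> RasterStack:
    """Resample layers onto ``target``: continuous bilinearly, categorical nearest.

    A layer already on the target grid is passed through unchanged.  Any
    nodata contributor makes the output cell nodata.  Layers must share the
    target CRS; there is no reprojection engine here.
    """
    out = RasterStack()
    for layer in layers:
        if layer.grid.crs_id != target.crs_id:
            raise ValueError(
                f"layer {layer.name!r} CRS {layer.grid.crs_id!r} does not match "
                f"target CRS {target.crs_id!r} and no transform is defined"
            )
        if layer.grid == target:
            out.add(layer.copy())
            continue
        if layer.kind == CATEGORICAL:
            vals = _resample_nearest(layer, target)
        else:
            vals = _resample_bilinear(layer, target)
        out.add(RasterLayer(layer.name, target, vals, kind=layer.kind))
    return out


# ---------------------------------------------------------------------------
# Terrain derivatives


def _horn_gradients(elev: RasterLayer) -> tuple[np.ndarray, np.ndarray]:
    z = elev.values
    cs = elev.grid.cell_size
    # 8-neighbour views of the interior; row 0 is north so +y is -row
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    # grouped so constant fields cancel exactly
    dzdx_i = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    dzdy_i = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)
    dzdx = np.full_like(z, np.nan)
    dzdy = np.full_like(z, np.nan)
    dzdx[1:-1, 1:-1] = dzdx_i
    dzdy[1:-1, 1:-1] = dzdy_i
    return dzdx, dzdy


def slope_aspect(elev: RasterLayer) -> tuple[RasterLayer, RasterLayer]:
    """Slope (degrees) and geographic aspect (degrees clockwise from north).

    Aspect is the downslope direction; flat cells get nodata aspect (their
    usable aspect components are produced by :func:`eastness_northness`).
    Edge cells are nodata.
    """
    if elev.grid.n_rows < 3 or elev.grid.n_cols < 3:
        raise ValueError("slope/aspect needs at least a 3x3 raster")
    dzdx, dzdy = _horn_gradients(elev)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope vector in (east, north) components
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = np.nan
    return (
        RasterLayer("slope_deg", elev.grid, slope),
        RasterLayer("aspect_deg", elev.grid, aspect),
    )


def eastness_northness(aspect: RasterLayer, slope: RasterLayer | None = None) -> tuple[RasterLayer, RasterLayer]:
    """sin/cos of aspect; flat cells (aspect nodata, slope 0) map to (0, 0)."""
    a = np.radians(aspect.values)
    east = np.sin(a)
    north = np.cos(a)
    if slope is not None:
        flat = slope.values == 0
        east[flat] = 0.0
        north[flat] = 0.0
    return (
        RasterLayer("eastness", aspect.grid, east),
        RasterLayer("northness", aspect.grid, north),
    )


_NEIGHBOUR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def tri_3x3(elev: RasterLayer, variant: str = "mean-abs") -> RasterLayer:
    """Terrain ruggedness index over the 8-neighbourhood.

    ``variant='mean-abs'`` (default) is the mean absolute difference between
    the cell and its neighbours; ``variant='rss'`` the root-sum-of-squares
    alternative.  Edge cells are nodata.
    """
    z = elev.values
    nr, nc = z.shape
    acc = np.zeros((nr - 2, nc - 2))
    centre = z[1:-1, 1:-1]
    for dr, dc in _NEIGHBOUR_OFFSETS:
        nb = z[1 + dr : nr - 1 + dr, 1 + dc : nc - 1 + dc]
        d = nb - centre
        acc += d * d if variant == "rss" else np.abs(d)
    if variant == "rss":
        inner = np.sqrt(acc)
    elif variant == "mean-abs":
        inner = acc / 8.0
    else:
        raise ValueError(f"unknown TRI variant {variant!r}")
    out = np.full_like(z, np.nan)
    out[1:-1, 1:-1] = inner
    return RasterLayer("TRI_3x3", elev.grid, out)


def tpi(elev: RasterLayer, radius_m: float) -> RasterLayer:
    """Topographic position index: cell minus mean over a circular window.

    The window contains every cell whose centre lies within ``radius_m`` of
    the focal cell centre, the focal cell excluded.  Positive on ridges and
    knolls, negative in valleys.  Cells with an entirely-nodata window are
    nodata; windows are clipped at the raster edge.
    """
    cs = elev.grid.cell_size
    if radius_m < cs:
        raise ValueError(f"TPI radius {radius_m} m is smaller than one cell ({cs} m)")
    r_cells = int(np.floor(radius_m / cs))
    dy, dx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    footprint = ((dy * cs) ** 2 + (dx * cs) ** 2) <= radius_m**2
    footprint[r_cells, r_cells] = False
    z = elev.values
    finite = np.isfinite(z)
    zfilled = np.where(finite, z, 0.0)
    ssum = convolve(zfilled, footprint.astype(float), mode="constant", cval=0.0)
    scount = convolve(finite.astype(float), footprint.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(scount > 0, ssum / scount, np.nan)
    out = z - mean
    name = f"TPI_{int(round(radius_m))}m"
    return RasterLayer(name, elev.grid, out)


def derive_terrain(elev: RasterLayer, tpi_radii_m: Sequence[float] = (300.0, 900.0)) -> RasterStack:
    """All terrain predictors from an elevation layer, as a stack."""
    slope, aspect = slope_aspect(elev)
    east, north = eastness_northness(aspect, slope)
    layers = [elev.copy(), slope, east, north, tri_3x3(elev)]
    layers += [tpi(elev, r) for r in tpi_radii_m]
    return RasterStack(layers)


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class StandardizationParams:
    """Per-predictor mean/sd over the reference cell set, for z-scoring.

    The same parameters are applied to point extractions so training rows and
    map predictions share one scale, and allow the inverse (affine) mapping.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, name: str, values: np.ndarray) -> np.ndarray:
        return (values - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z: np.ndarray) -> np.ndarray:
        return z * self.sds[name] + self.means[name]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"means": self.means, "sds": self.sds}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(means=d["means"], sds=d["sds"])


def standardize(
    stack: RasterStack, reference_cells: np.ndarray | None = None
) -> tuple[RasterStack, StandardizationParams]:
    """Z-score continuous layers over ``reference_cells`` (default: all finite).

    Categorical layers pass through untouched.  A zero-variance continuous
    layer raises :class:`DegeneratePredictorError` naming the layer.
    """
    params = StandardizationParams()
    out = RasterStack()
    for name in stack.names:
        layer = stack[name]
        if layer.kind != CONTINUOUS:
            out.add(layer.copy())
            continue
        ref = reference_cells if reference_cells is not None else np.isfinite(layer.values)
        vals = layer.values[ref]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise DegeneratePredictorError(f"layer {name!r}: fewer than 2 reference values")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=0))
        if sd <= 0:
            raise DegeneratePredictorError(f"layer {name!r} has zero variance over reference cells")
        params.means[name] = mean
        params.sds[name] = sd
        out.add(RasterLayer(name, layer.grid, (layer.values - mean) / sd, kind=CONTINUOUS))
    return out, params
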