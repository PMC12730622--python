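"""Prediction-domain construction: limestone presence x elevation band.

The analysis domain is the intersection of the categorical limestone layer
with an elevation band derived from the occurrences (P5-P95 of occurrence
elevations, buffered -100 m / +200 m), restricted to cells where every
predictor is defined.  The limestone layer itself is excluded from the
predictor set downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid, RasterLayer, RasterStack, write_ascii_grid

PERCENTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint")


@dataclass(frozen=True)
class ElevationBand:
    """Buffered percentile band of occurrence elevations, in metres a.s.l."""

    lo: float
    hi: float
    p_low: float = 5.0
    p_high: float = 95.0
    buffer_low: float = -100.0
    buffer_high: float = 200.0

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"elevation band is empty: lo {self.lo} >= hi {self.hi}")
        if self.p_low >= self.p_high:
            raise ValueError("p_low must be below p_high")


@dataclass
class DomainMask:
    """Boolean cell membership of the prediction domain, with provenance."""

    grid: Grid
    cells: np.ndarray
    band: ElevationBand
    limestone_layer: str = "limestone_bin"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, bool)
        if self.cells.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    def to_layer(self) -> RasterLayer:
        return RasterLayer("domain_mask", self.grid, self.cells.astype(float), kind="categorical")

    def write(self, path) -> None:
        write_ascii_grid(self.to_layer(), path)


def elevation_band(
    occ_elevations,
    p_low: float = 5.0,
    p_high: float = 95.0,
    buffer_low: float = -100.0,
    buffer_high: float = 200.0,
    method: str = "linear",
) -> ElevationBand:
    """Buffered P5-P95 band of the occurrence elevations.

    ``method`` selects the percentile convention (numpy's names); linear
    interpolation between order statistics is the default.
    """
    elev = np.asarray(occ_elevations, float)
    elev = elev[np.isfinite(elev)]
    if elev.size < 2:
        raise ValueError("need at least 2 occurrence elevations for a band")
    if method not in PERCENTILE_METHODS:
        raise ValueError(f"unknown percentile method {method!r}")
    lo = float(np.percentile(elev, p_low, method=method)) + buffer_low
    hi = float(np.percentile(elev, p_high, method=method)) + buffer_high
    return ElevationBand(lo=lo, hi=hi, p_low=p_low, p_high=p_high,
                         buffer_low=buffer_low, buffer_high=buffer_high)


def build_mask(
    stack: RasterStack,
    band: ElevationBand,
    limestone_layer: str = "limestone_bin",
    elevation_layer: str = "elev_m",
) -> DomainMask:
    """Limestone AND in-band AND all-predictors-defined cell mask.

    Raises with diagnostic counts when the intersection is empty.
    """
    for required in (limestone_layer, elevation_layer):
        if required not in stack:
            raise ValueError(f"stack has no {required!r} layer")
    lime = stack[limestone_layer].values == 1
    elev = stack[elevation_layer].values
    in_band = np.isfinite(elev) & (elev >= band.lo) & (elev <= band.hi)
    complete = np.ones(stack.grid.shape, dtype=bool)
    for name in stack.names:
        complete &= np.isfinite(stack[name].values)
    cells = lime & in_band & complete
    diagnostics = {
        "n_limestone": int(lime.sum()),
        "n_in_band": int(in_band.sum()),
        "n_complete": int(complete.sum()),
        "n_mask": int(cells.sum()),
        "band_lo": band.lo,
        "band_hi": band.hi,
    }
    if not cells.any():
        raise ValueError(f"empty prediction domain: {diagnostics}")
    return DomainMask(
        grid=stack.grid,
        cells=cells,
        band=band,
        limestone_layer=limestone_layer,
        diagnostics=diagnostics,
    )
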