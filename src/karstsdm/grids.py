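"""Raster grid containers and plain-text raster I/O.

The package works on small projected raster stacks (metres, row 0 at the
northern edge).  Layers are held in memory as 2-D float arrays with ``NaN``
marking nodata; the sentinel value in :class:`Grid` is only used when a layer
is written to disk.  Rasters round-trip through ESRI ASCII grid files (a
plain-text format readable by every GIS) with a JSON sidecar carrying layer
kind and CRS identifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class Grid:
    """A regular projected grid.

    ``origin_x``/``origin_y`` locate the *top-left corner* of the top-left
    cell; rows increase southwards, columns eastwards.  ``cell_size`` is in
    metres.  ``nodata`` is the on-disk sentinel; in memory nodata is NaN.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "local-metres"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x, y coordinates of cell centres for (row, col) indices."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col containing each point; cells are half-open [edge, edge)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class RasterLayer:
    """A named single-band raster on a :class:`Grid`."""

    name: str
    grid: Grid
    values: np.ndarray
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid shape {self.grid.shape}"
            )
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == CATEGORICAL:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.allclose(finite, np.round(finite)):
                raise ValueError(f"categorical layer {self.name!r} has non-integer codes")

    def copy(self, **updates) -> "RasterLayer":
        kw = dict(name=self.name, grid=self.grid, values=self.values.copy(), kind=self.kind)
        kw.update(updates)
        return RasterLayer(**kw)

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


class RasterStack(Mapping[str, RasterLayer]):
    """An ordered collection of grid-aligned layers."""

    def __init__(self, layers: Sequence[RasterLayer] = ()):
        self._layers: dict[str, RasterLayer] = {}
        for layer in layers:
            self.add(layer)

    def add(self, layer: RasterLayer) -> None:
        if self._layers:
            if layer.grid != self.grid:
                raise ValueError(
                    f"layer {layer.name!r} grid does not match stack grid"
                )
        if layer.name in self._layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        self._layers[layer.name] = layer

    @property
    def grid(self) -> Grid:
        if not self._layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self._layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def continuous_names(self) -> list[str]:
        return [n for n, l in self._layers.items() if l.kind == CONTINUOUS]

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def to_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack layer values into an (n_layers, n_rows, n_cols) array."""
        names = list(names) if names is not None else self.names
        return np.stack([self._layers[n].values for n in names])

    def extract(self, x: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        """Layer values at the cells containing the points; out-of-grid -> NaN."""
        names = list(names) if names is not None else self.names
        row, col = self.grid.point_to_cell(x, y)
        inside = self.grid.contains(row, col)
        out = np.full((len(np.atleast_1d(row)), len(names)), np.nan)
        r = np.atleast_1d(row)[inside]
        c = np.atleast_1d(col)[inside]
        for j, n in enumerate(names):
            out[inside, j] = self._layers[n].values[r, c]
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid round-trip


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    g = layer.grid
    path = Path(path)
    vals = np.where(np.isfinite(layer.values), layer.values, g.nodata)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {g.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"name": layer.name, "kind": layer.kind, "crs_id": g.crs_id}))


def read_ascii_grid(path: str | Path) -> RasterLayer:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    meta = {"name": path.stem, "kind": CONTINUOUS, "crs_id": "local-metres"}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    grid = Grid(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        crs_id=meta["crs_id"],
        nodata=nodata,
    )
    return RasterLayer(meta["name"], grid, vals, kind=meta["kind"])


def write_stack(stack: RasterStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.names:
        p = directory / f"{name}.asc"
        write_ascii_grid(stack[name], p)
        paths.append(p)
    return paths


def read_stack(directory: str | Path) -> RasterStack:
    directory = Path(directory)
    layers = [read_ascii_grid(p) for p in sorted(directory.glob("*.asc"))]
    if not layers:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    return RasterStack(layers)
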