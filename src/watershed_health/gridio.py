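"""Raster layer I/O as ESRI ASCII grids (plain text, one file per layer)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synthetic_data import LandscapeGrid

NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, cell_size: float, xll: float = 0.0, yll: float = 0.0) -> None:
    array = np.asarray(array, dtype=float)
    n_rows, n_cols = array.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {xll}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Return (array, cell_size); NODATA cells become NaN."""
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            meta[key.lower()] = float(value)
        array = np.loadtxt(fh)
    array = array.reshape(int(meta["nrows"]), int(meta["ncols"]))
    nodata = meta.get("nodata_value", NODATA)
    array = np.where(array == nodata, np.nan, array)
    return array, meta["cellsize"]


def write_landscape(grid: LandscapeGrid, directory) -> None:
    """One ASCII grid per landscape layer in the given directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in grid.layers().items():
        write_ascii_grid(directory / f"{name}.asc", layer, grid.cell_size)


def read_landscape(directory) -> LandscapeGrid:
    directory = Path(directory)
    layers = {}
    cell_size = None
    for name in ("elevation", "precip", "aet", "tree_frac", "pasture_frac", "population", "cattle"):
        layers[name], cell_size = read_ascii_grid(directory / f"{name}.asc")
    return LandscapeGrid(cell_size=cell_size, **layers)
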