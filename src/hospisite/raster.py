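"""Regular grid rasters and ESRI ASCII grid I/O.

Row 0 is the minimum-y row; cell (r, c) has its centre at
``(x0 + (c + 0.5) * cell, y0 + (r + 0.5) * cell)``.  The ESRI ASCII
format stores the top row first, so reading/writing flips row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "make_grid", "write_ascii_grid", "read_ascii_grid"]

NODATA = -9999.0


@dataclass
class GridRaster:
    x0_km: float
    y0_km: float
    cell_size_km: float
    values: np.ndarray = field(repr=False)  # shape (n_rows, n_cols), row 0 = min y

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_rows, n_cols)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        c = self.cell_size_km
        return (self.x0_km + (col + 0.5) * c, self.y0_km + (row + 0.5) * c)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) 1-D arrays of column / row centre coordinates."""
        c = self.cell_size_km
        xs = self.x0_km + (np.arange(self.n_cols) + 0.5) * c
        ys = self.y0_km + (np.arange(self.n_rows) + 0.5) * c
        return xs, ys

    def same_geometry(self, other: "GridRaster", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0_km - other.x0_km) <= tol
            and abs(self.y0_km - other.y0_km) <= tol
            and abs(self.cell_size_km - other.cell_size_km) <= tol
        )

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        return GridRaster(self.x0_km, self.y0_km, self.cell_size_km,
                          np.asarray(values, dtype=float))

    def integral(self) -> float:
        """Sum of value x cell area (weight units when values are per km^2)."""
        return float(self.values.sum() * self.cell_size_km**2)


def make_grid(bounds: tuple[float, float, float, float],
              cell_size_km: float) -> GridRaster:
    """Zero-initialised grid covering ``bounds`` (ceiling rule on extent)."""
    xmin, ymin, xmax, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounds")
    if cell_size_km <= 0:
        raise ValueError("cell_size_km must be positive")
    n_cols = math.ceil((xmax - xmin) / cell_size_km)
    n_rows = math.ceil((ymax - ymin) / cell_size_km)
    return GridRaster(xmin, ymin, cell_size_km, np.zeros((n_rows, n_cols)))


def write_ascii_grid(raster: GridRaster, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.x0_km)!r}\n")
        fh.write(f"yllcorner {float(raster.y0_km)!r}\n")
        fh.write(f"cellsize {float(raster.cell_size_km)!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in raster.values[::-1]:  # ESRI ASCII: top row first
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


def read_ascii_grid(path: str | Path) -> GridRaster:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    values = np.array(rows, dtype=float)[::-1]
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape does not match header")
    return GridRaster(header["xllcorner"], header["yllcorner"],
                      header["cellsize"], values)
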