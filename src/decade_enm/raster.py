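"""Gridded environmental layers: the :class:`RasterStack` container and text I/O.

A stack is a set of co-registered single-band rasters sharing one grid
(rows, columns, lower-left origin, square cell) and one validity mask.
Rows are stored top-down (row 0 is the northernmost), matching how ESRI
ASCII grids are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["RasterStack", "read_ascii_grid", "write_ascii_grid", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when layers do not share grid shape, origin, or cell size."""


@dataclass
class RasterStack:
    """Aligned environmental layers with a shared validity mask.

    Parameters
    ----------
    data
        Array of shape ``(n_layers, n_rows, n_cols)``. Cells that are
        nodata in *any* layer are masked everywhere (mask-union rule).
    x_origin, y_origin
        Coordinates of the lower-left corner of the grid.
    cell_size
        Side length of the square cells, in the same units as the origin.
    valid
        Boolean ``(n_rows, n_cols)`` array, ``True`` where all layers
        hold data.
    names
        Optional layer names; defaults to ``layer_0 .. layer_{k-1}``.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    valid: np.ndarray | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_layers, n_rows, n_cols)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.data), axis=0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape[1:]:
                raise AlignmentError("valid mask shape does not match layers")
            self.valid = self.valid & np.all(np.isfinite(self.data), axis=0)
        self.data[:, ~self.valid] = np.nan
        if not self.names:
            self.names = [f"layer_{i}" for i in range(self.n_layers)]
        if len(self.names) != self.n_layers:
            raise ValueError("names length must equal number of layers")

    # -- geometry -----------------------------------------------------
    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_cols(self) -> int:
        return self.data.shape[2]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        return (
            self.x_origin,
            self.y_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin + self.n_rows * self.cell_size,
        )

    def same_grid(self, other: "RasterStack", rtol: float = 1e-9) -> bool:
        return (
            self.data.shape[1:] == other.data.shape[1:]
            and math.isclose(self.x_origin, other.x_origin, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.y_origin, other.y_origin, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=rtol, abs_tol=1e-12)
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (row, col) indices to the x, y coordinates of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to containing (row, col) cell indices.

        Membership is half-open: a point on a shared edge belongs to the
        cell to its lower-left in index space. Points outside the extent
        raise ``IndexError`` listing the offending positions.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y_origin) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if bad.any():
            idx = np.flatnonzero(bad)
            raise IndexError(f"points outside raster extent at indices {idx.tolist()}")
        return row, col

    # -- value access --------------------------------------------------
    def values_matrix(self) -> np.ndarray:
        """Return an ``(n_valid_cells, n_layers)`` matrix of layer values."""
        return self.data[:, self.valid].T

    def valid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.valid)

    def with_data(self, data: np.ndarray, names: Sequence[str] | None = None) -> "RasterStack":
        """New stack on the same grid/mask carrying different layer values."""
        return RasterStack(
            data=np.asarray(data, dtype=float),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            valid=self.valid.copy(),
            names=list(names) if names is not None else [],
        )


# ---------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> RasterStack:
    """Read a single-band ESRI ASCII grid (.asc) as a one-layer stack."""
    path = Path(path)
    header: dict[str, float] = {}
    nodata = -9999.0
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                key = parts[0].lower()
                if key == "nodata_value":
                    nodata = float(parts[1])
                else:
                    header[key] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise ValueError(f"{path}: ASCII grid header missing {missing}")
        body = np.loadtxt(fh, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    body = body.reshape(n_rows, n_cols)
    data = np.where(body == nodata, np.nan, body)
    return RasterStack(
        data=data[None, :, :],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        names=[path.stem],
    )


def write_ascii_grid(stack: RasterStack, path: str | Path, layer: int = 0,
                     nodata: float = -9999.0, fmt: str = "%.6g") -> Path:
    """Write one layer of a stack as an ESRI ASCII grid."""
    path = Path(path)
    band = stack.data[layer]
    out = np.where(stack.valid & np.isfinite(band), band, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {stack.n_cols}\n")
        fh.write(f"nrows {stack.n_rows}\n")
        fh.write(f"xllcorner {stack.x_origin:.10g}\n")
        fh.write(f"yllcorner {stack.y_origin:.10g}\n")
        fh.write(f"cellsize {stack.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)
    return path


def stack_layers(stacks: Iterable[RasterStack]) -> RasterStack:
    """Combine single-layer stacks into one multi-layer stack.

    The unified validity mask is the intersection of per-layer masks
    (equivalently: a cell nodata anywhere is nodata everywhere).
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("need at least one layer")
    first = stacks[0]
    for s in stacks[1:]:
        if not first.same_grid(s):
            raise AlignmentError(
                "layer grids differ in shape, origin, or cell size"
            )
    data = np.concatenate([s.data for s in stacks], axis=0)
    valid = np.logical_and.reduce([s.valid for s in stacks])
    names = [n for s in stacks for n in s.names]
    return RasterStack(
        data=data,
        x_origin=first.x_origin,
        y_origin=first.y_origin,
        cell_size=first.cell_size,
        valid=valid,
        names=names,
    )
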