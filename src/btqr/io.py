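"""Plain-text raster and point I/O.

Rasters are read and written as ESRI ASCII grids (the ``.asc`` header
format with ``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``) or
as headerless whitespace-delimited text grids with a declared nodata
sentinel.  Points come from CSV with either (row, col) cell indices or
(x, y) map coordinates resolved through the ASCII-grid geotransform.

Conventions: grid indexing is 0-based (row, col) with row 0 the raster's
top line; coordinates use cell-center registration.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridError, SuitabilityGrid
from .pe_curve import PECurve, PresencePoints, extract_suitability

__all__ = [
    "GeoTransform",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "pe_curve_to_frame",
    "write_pe_curve",
]

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass(frozen=True)
class GeoTransform:
    """Affine placement of a grid: lower-left corner and square cell size."""

    xllcorner: float
    yllcorner: float
    cellsize: float
    nrows: int
    ncols: int

    def xy_to_cell(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row = self.nrows - 1 - int(np.floor((y - self.yllcorner) / self.cellsize))
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (self.nrows - 1 - row + 0.5) * self.cellsize
        return x, y


def read_raster(path, nodata: float | None = None
                ) -> tuple[SuitabilityGrid, GeoTransform | None]:
    """Read a suitability raster from an ESRI ASCII grid or bare text grid.

    An ASCII-grid header is auto-detected (first token alphabetic).  For
    headerless grids a ``nodata`` sentinel may be supplied (e.g. -9999);
    for ASCII grids the header's NODATA_value is honored, overridden by an
    explicit ``nodata`` argument.  Values outside [0, 1] (after masking)
    raise with the offending range named.

    Returns the grid and, for ASCII grids, its geotransform (``None`` for
    headerless grids — indices-only mode).
    """
    with open(path) as fh:
        text = fh.read()
    first = text.lstrip().split(None, 1)[0] if text.strip() else ""
    header: dict[str, float] = {}
    body = text
    if first and first[0].isalpha():
        lines = text.splitlines()
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        body = "\n".join(lines[i:])
        missing = [k for k in _ASC_KEYS if k not in header]
        if missing:
            raise GridError(f"ASCII grid header missing keys: {missing}")
    values = np.loadtxt(_io.StringIO(body), ndmin=2)
    transform = None
    if header:
        nr, nc = int(header["nrows"]), int(header["ncols"])
        if values.shape != (nr, nc):
            raise GridError(
                f"grid body shape {values.shape} != header ({nr}, {nc})"
            )
        transform = GeoTransform(header["xllcorner"], header["yllcorner"],
                                 header["cellsize"], nr, nc)
        if nodata is None and "nodata_value" in header:
            nodata = header["nodata_value"]
    mask = None
    if nodata is not None:
        mask = values != nodata
    grid = SuitabilityGrid(values, mask)
    return grid, transform


def write_raster(path, grid: SuitabilityGrid,
                 transform: GeoTransform | None = None,
                 nodata: float = -9999.0, fmt: str = "%.10g",
                 values: np.ndarray | None = None) -> None:
    """Write a grid (or a same-shape ``values`` array, e.g. a binary map)."""
    vals = grid.values if values is None else np.asarray(values, dtype=float)
    out = np.where(grid.mask, vals, nodata)
    with open(path, "w") as fh:
        if transform is not None:
            fh.write(f"ncols {transform.ncols}\n"
                     f"nrows {transform.nrows}\n"
                     f"xllcorner {transform.xllcorner!r}\n"
                     f"yllcorner {transform.yllcorner!r}\n"
                     f"cellsize {transform.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n" if transform is not None else "")
        np.savetxt(fh, out, fmt=fmt)


def read_points(path, grid: SuitabilityGrid, mode: str = "index",
                transform: GeoTransform | None = None,
                on_nodata: str = "error") -> PresencePoints:
    """Read presence points from CSV and resolve them against a grid.

    ``mode="index"`` expects columns ``row, col``; ``mode="coordinate"``
    expects ``x, y`` and needs the raster's geotransform.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if mode == "index":
        if "row" not in cols or "col" not in cols:
            raise ValueError(
                f"expected columns 'row' and 'col', found {list(df.columns)}"
            )
        cells = df[[cols["row"], cols["col"]]].to_numpy(dtype=int)
    elif mode == "coordinate":
        if "x" not in cols or "y" not in cols:
            raise ValueError(
                f"expected columns 'x' and 'y', found {list(df.columns)}"
            )
        if transform is None:
            raise ValueError("coordinate mode requires a raster geotransform")
        cells = np.array([transform.xy_to_cell(x, y)
                          for x, y in df[[cols["x"], cols["y"]]].to_numpy()])
    else:
        raise ValueError("mode must be 'index' or 'coordinate'")
    return extract_suitability(grid, cells, on_nodata=on_nodata)


def write_points(path, cells: np.ndarray) -> None:
    pd.DataFrame(np.atleast_2d(cells), columns=["row", "col"]).to_csv(
        path, index=False)


def pe_curve_to_frame(curve: PECurve) -> pd.DataFrame:
    """Tidy per-class table of a P/E curve."""
    return pd.DataFrame({
        "class_index": np.round(curve.class_edges[:, 0] * curve.n_classes
                                ).astype(int),
        "hs_lo": curve.class_edges[:, 0],
        "hs_hi": curve.class_edges[:, 1],
        "hs_mean": curve.hs_mean,
        "p_count": curve.p_counts,
        "a_count": curve.a_counts,
        "P": curve.P,
        "E": curve.E,
        "F": curve.F,
    })


def write_pe_curve(path, curve: PECurve) -> None:
    pe_curve_to_frame(curve).to_csv(path, index=False)
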