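"""Container for continuous habitat-suitability surfaces.

A :class:`SuitabilityGrid` holds the continuous output of a species
distribution model over a rectangular landscape: one value per grid cell in
``[0, 1]`` plus a validity mask for nodata cells (sea, outside the study
area, ...).  All downstream machinery — P/E curves, threshold selection,
prevalence estimation — operates on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridError(ValueError):
    """Raised for malformed suitability grids or invalid cell access."""


@dataclass(frozen=True)
class SuitabilityGrid:
    """A 2-D field of continuous habitat-suitability predictions.

    Parameters
    ----------
    values
        2-D float array.  Cells outside the mask may hold anything (they are
        ignored); valid cells must lie in ``[0, 1]``.
    mask
        2-D boolean array of the same shape; ``True`` marks a valid cell.
        ``None`` means every cell is valid.

    Notes
    -----
    The grid is the sampling frame for the "expected" side of the P/E curve:
    the per-class valid-cell counts ``a_i`` and their total are taken from it.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise GridError(f"values must be 2-D, got shape {values.shape}")
        if self.mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != values.shape:
                raise GridError(
                    f"mask shape {mask.shape} != values shape {values.shape}"
                )
        # NaNs in the data are treated as nodata regardless of the mask.
        mask = mask & ~np.isnan(values)
        if not mask.any():
            raise GridError("grid has no valid cells")
        valid = values[mask]
        if valid.min() < 0.0 or valid.max() > 1.0:
            raise GridError(
                "valid cell values must lie in [0, 1]; observed range "
                f"[{valid.min():.6g}, {valid.max():.6g}]"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        """Number of valid cells (the total cell count ``sum a_j``)."""
        return int(self.mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of the suitability values on valid cells."""
        return self.values[self.mask]

    def in_bounds(self, row: int, col: int) -> bool:
        nrows, ncols = self.shape
        return 0 <= row < nrows and 0 <= col < ncols

    def value_at(self, row: int, col: int) -> float:
        """Suitability at a cell; raises for out-of-bounds or nodata cells."""
        if not self.in_bounds(row, col):
            raise GridError(f"cell ({row}, {col}) is outside the grid extent")
        if not self.mask[row, col]:
            raise GridError(f"cell ({row}, {col}) is a nodata cell")
        return float(self.values[row, col])
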