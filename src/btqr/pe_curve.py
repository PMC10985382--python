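"""Predicted-to-expected (P/E) curves from presence-only validation data.

The Boyce evaluation framework needs no absence records: the suitability
range [0, 1] is divided into ``1/W`` classes of width ``W`` and, per class
``i``, the frequency of validation presences

    P_i = p_i / sum_j p_j

is compared with the frequency expected under a uniform random placement
over the landscape,

    E_i = a_i / sum_j a_j,

where ``p_i`` counts validation points and ``a_i`` counts valid grid cells
in the class.  The ratio ``F_i = P_i / E_i`` exceeds 1 wherever the model
concentrates presences beyond chance.  Plotting ``F_i`` against the mean
suitability of each class yields the P/E curve whose shape carries the
habitat-quality signal used for threshold selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import GridError, SuitabilityGrid

__all__ = [
    "PresencePoints",
    "PECurve",
    "extract_suitability",
    "compute_pe_curve",
]


@dataclass(frozen=True)
class PresencePoints:
    """Validation presence records resolved to grid cells.

    ``cells`` is an (n, 2) integer array of (row, col) indices and
    ``suitabilities`` the grid values extracted at those cells, in the same
    order.  Points are counted per record, not per unique cell: two records
    on the same cell contribute two validation points.
    """

    cells: np.ndarray
    suitabilities: np.ndarray

    def __post_init__(self) -> None:
        cells = np.atleast_2d(np.asarray(self.cells, dtype=int))
        suit = np.asarray(self.suitabilities, dtype=float)
        if cells.shape[0] != suit.shape[0]:
            raise ValueError("cells and suitabilities lengths differ")
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "suitabilities", suit)

    def __len__(self) -> int:
        return self.suitabilities.shape[0]


@dataclass(frozen=True)
class PECurve:
    """Per-class records of a predicted-to-expected curve.

    Only classes with positive area (``a_i > 0``) are retained; a retained
    class with no presences keeps ``F_i = 0``.  ``hs_mean`` is the mean
    suitability of the grid cells in each class (not the bin midpoint), so
    it is strictly increasing across retained classes.
    """

    class_edges: np.ndarray  # (n_retained, 2) [lo, hi) bins, last closed
    hs_mean: np.ndarray
    p_counts: np.ndarray
    a_counts: np.ndarray
    P: np.ndarray
    E: np.ndarray
    F: np.ndarray
    n_classes: int  # b = 1/W, before dropping empty classes
    window_width: float

    @property
    def n_retained(self) -> int:
        return self.hs_mean.shape[0]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.hs_mean) <= 0):
            raise ValueError("hs_mean must be strictly increasing across classes")
        if np.any(self.F < 0):
            raise ValueError("F must be non-negative")


def extract_suitability(grid: SuitabilityGrid, points, *,
                        on_nodata: str = "error") -> PresencePoints:
    """Look up suitability values at presence locations.

    Parameters
    ----------
    grid
        The suitability surface.
    points
        Sequence of (row, col) cell indices.
    on_nodata
        ``"error"`` rejects points on nodata cells; ``"drop"`` removes them
        with a warning.  Out-of-extent points always raise.
    """
    if on_nodata not in ("error", "drop"):
        raise ValueError("on_nodata must be 'error' or 'drop'")
    pts = np.atleast_2d(np.asarray(points, dtype=int))
    if pts.size == 0:
        return PresencePoints(np.empty((0, 2), dtype=int), np.empty(0))
    if pts.shape[1] != 2:
        raise ValueError("points must be (row, col) pairs")
    nrows, ncols = grid.shape
    oob = (pts[:, 0] < 0) | (pts[:, 0] >= nrows) | (pts[:, 1] < 0) | (pts[:, 1] >= ncols)
    if oob.any():
        bad = pts[oob][0]
        raise GridError(
            f"point ({bad[0]}, {bad[1]}) is outside the grid extent "
            f"{nrows}x{ncols}"
        )
    on_bad = ~grid.mask[pts[:, 0], pts[:, 1]]
    if on_bad.any():
        if on_nodata == "error":
            bad = pts[on_bad][0]
            raise GridError(f"point ({bad[0]}, {bad[1]}) falls on a nodata cell")
        warnings.warn(
            f"dropping {int(on_bad.sum())} presence point(s) on nodata cells",
            stacklevel=2,
        )
        pts = pts[~on_bad]
    return PresencePoints(pts, grid.values[pts[:, 0], pts[:, 1]])


def _class_index(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Bin assignment: half-open [lo, hi) bins, final bin closed at 1."""
    edges = np.arange(1, n_classes) / n_classes
    idx = np.searchsorted(edges, values, side="right")
    return idx


def compute_pe_curve(grid: SuitabilityGrid, presences: PresencePoints,
                     window_width: float = 0.01) -> PECurve:
    """Build the P/E curve at a given class width.

    ``window_width`` W partitions [0, 1] into ``1/W`` contiguous classes
    (W = 0.01 gives the customary 100-class resolution).  Bins are
    half-open ``[lo, hi)`` with the final bin closed so suitability 1 is
    counted.  Classes with zero area are dropped; classes with area but no
    presences keep ``F_i = 0``.
    """
    if len(presences) == 0:
        raise ValueError("presences must be non-empty")
    if not (0.0 < window_width <= 1.0):
        raise ValueError("window_width must lie in (0, 1]")
    b = 1.0 / window_width
    n_classes = int(round(b))
    if abs(b - n_classes) > 1e-9:
        raise ValueError(
            f"1/window_width must be an integer class count, got {b:.6g}"
        )

    cell_idx = _class_index(grid.valid_values, n_classes)
    pt_idx = _class_index(presences.suitabilities, n_classes)

    a_counts = np.bincount(cell_idx, minlength=n_classes).astype(int)
    p_counts = np.bincount(pt_idx, minlength=n_classes).astype(int)
    hs_sum = np.bincount(cell_idx, weights=grid.valid_values,
                         minlength=n_classes)

    retained = a_counts > 0
    if np.any(p_counts[~retained] > 0):  # pragma: no cover - presences sit on valid cells
        raise RuntimeError("presence point in a class with zero valid cells")

    P_all = p_counts / p_counts.sum()
    E_all = a_counts / a_counts.sum()

    P = P_all[retained]
    E = E_all[retained]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(E > 0, P / E, 0.0)

    lo = np.arange(n_classes)[retained] / n_classes
    hi = (np.arange(n_classes)[retained] + 1) / n_classes
    hs_mean = hs_sum[retained] / a_counts[retained]

    return PECurve(
        class_edges=np.column_stack([lo, hi]),
        hs_mean=hs_mean,
        p_counts=p_counts[retained],
        a_counts=a_counts[retained],
        P=P,
        E=E,
        F=F,
        n_classes=n_classes,
        window_width=window_width,
    )
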