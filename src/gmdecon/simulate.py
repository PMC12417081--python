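"""Aggregate single-cell-resolution spatial data into simulated multi-cell spots.

Imaging-based platforms (STARmap/osmFISH-like) measure single cells with
coordinates and type labels.  To benchmark deconvolution, the tissue landscape
is split into a rectangular grid at a fixed pixel interval; every cell is
assigned to the nearest grid center, each occupied grid becomes one multi-cell
spot whose expression is the sum of its members' raw counts and whose true
proportions are the members' type frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data import CellAnnotation, CountMatrix, SpotCoordinates


@dataclass
class SimulatedSpotSet:
    """Multi-cell spots aggregated from single cells on a grid."""

    counts: CountMatrix              # spots x genes, summed raw counts
    centers: np.ndarray              # (n_spots, 2) grid centers
    proportions: np.ndarray          # (n_spots, CT) realized true proportions
    type_names: List[str]
    cells_per_spot: np.ndarray       # (n_spots,) member counts
    cell_assignment: np.ndarray      # (n_cells,) spot index per retained cell

    def __post_init__(self) -> None:
        if np.any(self.cells_per_spot < 1):
            raise ValueError("every spot must contain at least one cell")
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")


def grid_centers(xy: np.ndarray, interval: float) -> np.ndarray:
    """Row-major grid centers at ``min + (k + 0.5) * interval`` covering the bounding box."""
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    n_x = max(1, int(np.ceil((hi[0] - lo[0]) / interval)))
    n_y = max(1, int(np.ceil((hi[1] - lo[1]) / interval)))
    cx = lo[0] + (np.arange(n_x) + 0.5) * interval
    cy = lo[1] + (np.arange(n_y) + 0.5) * interval
    gx, gy = np.meshgrid(cx, cy)  # row-major: y-rows, then x-columns
    return np.column_stack([gx.ravel(), gy.ravel()])


def grid_spots(
    cells: CountMatrix,
    coords: SpotCoordinates,
    labels: CellAnnotation,
    interval: float,
    exclude_types: Optional[Sequence[str]] = None,
) -> SimulatedSpotSet:
    """Assign each cell to its nearest grid center and aggregate into spots.

    Ties (a cell exactly equidistant to two centers) go to the lower row-major
    grid index.  Grids that receive no cells are dropped.  ``exclude_types``
    removes those cells entirely before gridding (e.g. types absent from the
    scRNA-seq reference).
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if cells.unit_ids != coords.unit_ids or cells.unit_ids != labels.unit_ids:
        raise ValueError("cells, coordinates and labels must share unit ids and order")

    keep = np.ones(cells.n_units, dtype=bool)
    if exclude_types:
        excluded = set(exclude_types)
        keep = np.array([t not in excluded for t in labels.cell_type])
        if not keep.any():
            raise ValueError("all cells excluded")
    xy = coords.xy[keep]
    values = cells.values[keep]
    type_names = [t for t in labels.types if not exclude_types or t not in set(exclude_types)]
    lut = {t: i for i, t in enumerate(type_names)}
    type_idx = np.array([lut[t] for t, k in zip(labels.cell_type, keep) if k])

    centers = grid_centers(xy, interval)
    d = cdist(xy, centers)
    assign = d.argmin(axis=1)  # argmin returns the first (lowest) index on ties

    occupied, assign_packed = np.unique(assign, return_inverse=True)
    n_spots = occupied.size
    counts = np.zeros((n_spots, cells.g), dtype=values.dtype)
    np.add.at(counts, assign_packed, values)
    type_counts = np.zeros((n_spots, len(type_names)))
    np.add.at(type_counts, (assign_packed, type_idx), 1.0)
    cells_per_spot = type_counts.sum(axis=1)
    proportions = type_counts / cells_per_spot[:, None]

    spot_ids = [f"spot_{g}" for g in occupied]
    return SimulatedSpotSet(
        counts=CountMatrix(counts, spot_ids, list(cells.gene_ids)),
        centers=centers[occupied],
        proportions=proportions,
        type_names=type_names,
        cells_per_spot=cells_per_spot.astype(int),
        cell_assignment=assign_packed,
    )
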