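"""Piecewise aperture dose model (PADM) on a dose influence matrix.

Dose to voxel *i* from one MLC leaf pair (row *m*) with continuous left/right
leaf positions ``(x, y)`` is built from the columns of a precomputed dose
influence matrix (DIM): bixels fully inside the opening contribute their full
DIM column, the (at most two) partially covered bixels contribute their column
scaled by the covered fraction of the bixel width.  The resulting dose is
piecewise linear and continuous in the leaf positions, and exactly reproduces
the plain column sum when the leaves sit on bixel boundaries.

Coordinates are continuous bixel units on a 0-based half-open grid: bixel *c*
spans ``[c, c+1)`` and the open field is the interval ``(x, y)`` with
``0 <= x <= y <= n_cols``.  A closed row (``x == y``) is legal and delivers
nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BixelGrid",
    "DoseInfluenceMatrix",
    "LeafRow",
    "Aperture",
    "AperturePlan",
    "RowDecomposition",
    "row_decomposition",
    "aperture_row_dose",
    "open_field_row_dose",
    "aperture_dose",
    "plan_dose",
]


@dataclass(frozen=True)
class BixelGrid:
    """Fluence-grid geometry of one beam: leaf rows x bixel columns."""

    beam_id: str
    n_rows: int
    n_cols: int
    bixel_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must have >=1 rows and columns, got {self.n_rows}x{self.n_cols}")
        if self.bixel_width <= 0:
            raise ValueError(f"bixel_width must be positive, got {self.bixel_width}")

    @property
    def n_bixels(self) -> int:
        return self.n_rows * self.n_cols

    def flat_index(self, row: int, col: int) -> int:
        """Flat bixel index of (row, col); row-major so a row is contiguous."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"bixel ({row},{col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def row_col(self, j: int) -> tuple[int, int]:
        """Inverse of :meth:`flat_index`."""
        if not (0 <= j < self.n_bixels):
            raise IndexError(f"flat bixel index {j} outside 0..{self.n_bixels - 1}")
        return divmod(j, self.n_cols)


class DoseInfluenceMatrix:
    """Sparse nonnegative map from bixel fluence to voxel dose (D_ij).

    Stored compressed-sparse-column over the flat (row-major) bixel index, so
    that the bixels of one leaf row are a contiguous column slice -- the hot
    path of annealing dose evaluation.
    """

    def __init__(self, grid: BixelGrid, values: sp.spmatrix | np.ndarray):
        values = sp.csc_matrix(values)
        if values.shape[1] != grid.n_bixels:
            raise ValueError(
                f"DIM has {values.shape[1]} columns but grid has {grid.n_bixels} bixels"
            )
        if values.nnz and values.data.min() < 0:
            raise ValueError("DIM entries must be nonnegative")
        self.grid = grid
        self.values = values

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def row_slice(self, m: int) -> sp.csc_matrix:
        """Columns of leaf row m (all n_cols bixels), as a CSC slice."""
        n_cols = self.grid.n_cols
        return self.values[:, m * n_cols : (m + 1) * n_cols]

    def column(self, m: int, c: int) -> np.ndarray:
        """Dense DIM column of bixel (m, c)."""
        j = self.grid.flat_index(m, c)
        return np.asarray(self.values[:, j].todense()).ravel()


@dataclass
class LeafRow:
    """One MLC leaf pair: left leaf at x, right leaf at y (bixel units)."""

    x: float
    y: float

    def validate(self, n_cols: int) -> None:
        if not (0.0 <= self.x <= self.y <= n_cols):
            raise ValueError(
                f"leaf row ({self.x}, {self.y}) violates 0 <= x <= y <= {n_cols}"
            )


@dataclass
class Aperture:
    """One deliverable MLC shape with a beam-on weight alpha >= 0."""

    beam_id: str
    weight: float
    rows: list[LeafRow]

    def validate(self, grid: BixelGrid) -> None:
        if self.weight < 0:
            raise ValueError(f"aperture weight must be >= 0, got {self.weight}")
        if len(self.rows) != grid.n_rows:
            raise ValueError(
                f"aperture has {len(self.rows)} rows, grid expects {grid.n_rows}"
            )
        for row in self.rows:
            row.validate(grid.n_cols)


@dataclass
class AperturePlan:
    """A fixed set of apertures across beams plus the per-beam DIMs."""

    apertures: list[Aperture]
    dims: dict[str, DoseInfluenceMatrix] = field(default_factory=dict)

    def validate(self) -> None:
        n_vox = {d.n_voxels for d in self.dims.values()}
        if len(n_vox) > 1:
            raise ValueError(f"beams disagree on voxel count: {sorted(n_vox)}")
        for ap in self.apertures:
            if ap.beam_id not in self.dims:
                raise ValueError(f"aperture references unknown beam {ap.beam_id!r}")
            ap.validate(self.dims[ap.beam_id].grid)

    @property
    def n_voxels(self) -> int:
        if not self.dims:
            raise ValueError("plan has no dose influence matrices")
        return next(iter(self.dims.values())).n_voxels


@dataclass(frozen=True)
class RowDecomposition:
    """Split of a leaf opening into partial and fully covered bixels.

    ``full`` is the half-open index range [start, stop) of fully covered
    bixels; each partial is (bixel index, covered fraction in (0, 1)).
    """

    left_partial: Optional[tuple[int, float]]
    full: tuple[int, int]
    right_partial: Optional[tuple[int, float]]


def row_decomposition(row: LeafRow, grid: BixelGrid) -> RowDecomposition:
    """Decompose the opening (x, y) into full bixels and partial overlaps.

    Full bixels are [ceil(x), floor(y)).  When x is non-integer the bixel
    ceil(x)-1 is partially covered with fraction ceil(x)-x; symmetrically the
    bixel floor(y) covers fraction y-floor(y).  When ceil(x) > floor(y) the
    opening lives inside a single bixel, covered with fraction y-x (the
    continuity-preserving extension for sub-bixel openings).
    """
    row.validate(grid.n_cols)
    x, y = row.x, row.y
    if x == y:
        return RowDecomposition(None, (0, 0), None)

    cx, fy = math.ceil(x), math.floor(y)
    if cx > fy:  # opening strictly inside one bixel
        return RowDecomposition((math.floor(x), y - x), (0, 0), None)

    left = None if x == cx else (cx - 1, cx - x)
    right = None if y == fy else (fy, y - fy)
    return RowDecomposition(left, (cx, fy), right)


def aperture_row_dose(row: LeafRow, m: int, dim: DoseInfluenceMatrix) -> np.ndarray:
    """Voxel dose f_ikm from one leaf row at unit aperture weight.

    Full bixels contribute their DIM column, partial bixels their column times
    the covered fraction; integer leaf positions reduce exactly to the plain
    column sum.
    """
    grid = dim.grid
    if not (0 <= m < grid.n_rows):
        raise IndexError(f"leaf row index {m} outside 0..{grid.n_rows - 1}")
    dec = row_decomposition(row, grid)

    base = m * grid.n_cols
    start, stop = dec.full
    if stop > start:
        dose = np.asarray(
            dim.values[:, base + start : base + stop].sum(axis=1)
        ).ravel()
    else:
        dose = np.zeros(dim.n_voxels)
    for partial in (dec.left_partial, dec.right_partial):
        if partial is not None:
            c, frac = partial
            dose += frac * dim.column(m, c)
    return dose


def open_field_row_dose(x: int, y: int, m: int, dim: DoseInfluenceMatrix) -> np.ndarray:
    """Plain column-sum dose for integer leaf positions (no partial bixels).

    Independent of :func:`aperture_row_dose`'s partial-bixel path; the two
    must agree bitwise whenever x and y are integers.
    """
    if x != int(x) or y != int(y):
        raise ValueError("open_field_row_dose requires integer leaf positions")
    base = m * dim.grid.n_cols
    return np.asarray(dim.values[:, base + int(x) : base + int(y)].sum(axis=1)).ravel()


def aperture_dose(ap: Aperture, dim: DoseInfluenceMatrix) -> np.ndarray:
    """Unit-weight dose of one aperture: sum of its row doses."""
    dose = np.zeros(dim.n_voxels)
    for m, row in enumerate(ap.rows):
        dose += aperture_row_dose(row, m, dim)
    return dose


def plan_dose(plan: AperturePlan) -> np.ndarray:
    """Total voxel dose of a plan: sum_k alpha_k * sum_m f_ikm.

    Linear in the aperture weight vector; a plan with all weights zero gives
    the zero dose.
    """
    plan.validate()
    dose = np.zeros(plan.n_voxels)
    for ap in plan.apertures:
        if ap.weight == 0.0:
            continue
        dose += ap.weight * aperture_dose(ap, plan.dims[ap.beam_id])
    return dose
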