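"""Shared fixtures: random DIMs, tiny cases, and independent dose oracles."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from rdao.dosemodel import BixelGrid, DoseInfluenceMatrix
from rdao.objective import Structure, StructureSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def dim_factory(rng):
    """Random sparse nonnegative DIM with a given geometry."""

    def make(n_voxels=50, n_rows=3, n_cols=6, density=0.5, beam_id="b"):
        grid = BixelGrid(beam_id, n_rows, n_cols)
        vals = rng.random((n_voxels, grid.n_bixels))
        vals[rng.random(vals.shape) > density] = 0.0
        return DoseInfluenceMatrix(grid, sp.csc_matrix(vals))

    return make


@pytest.fixture(scope="session")
def small_case():
    """Desk-scale C-shape case shared by the slower end-to-end tests."""
    from rdao.synthetic import make_case

    return make_case("c_shape", grid_shape=(24, 24, 12))


def interval_overlap_dose(dim: DoseInfluenceMatrix, m: int, x: float, y: float) -> np.ndarray:
    """Exact oracle: each bixel weighted by its geometric overlap with (x, y)."""
    n_cols = dim.grid.n_cols
    dose = np.zeros(dim.n_voxels)
    for c in range(n_cols):
        overlap = max(0.0, min(y, c + 1) - max(x, c))
        if overlap > 0:
            dose += overlap * dim.column(m, c)
    return dose


def sliver_dose(dim: DoseInfluenceMatrix, m: int, x: float, y: float, slivers=1000) -> np.ndarray:
    """Fine-subdivision oracle: sliver counted in if its center lies in (x, y)."""
    n_cols = dim.grid.n_cols
    dose = np.zeros(dim.n_voxels)
    for c in range(n_cols):
        centers = c + (np.arange(slivers) + 0.5) / slivers
        frac = np.mean((centers > x) & (centers < y))
        if frac > 0:
            dose += frac * dim.column(m, c)
    return dose


def two_bixel_toy():
    """1-row, 2-bixel, 2-voxel problem with a nonzero closed-form optimum.

    The rank-one influence matrix makes the system inconsistent, so the
    nonnegative least-squares optimum has positive cost.
    """
    from rdao.dosemodel import Aperture, AperturePlan, LeafRow

    D = np.array([[1.0, 1.0], [2.0, 2.0]])
    dim = DoseInfluenceMatrix(BixelGrid("b", 1, 2), sp.csc_matrix(D))
    structs = StructureSet(
        [Structure("t", np.array([0, 1]), 1.0, 1.0)], n_voxels=2
    )
    plan0 = AperturePlan(
        [
            Aperture("b", 0.5, [LeafRow(0.0, 2.0)]),
            Aperture("b", 0.5, [LeafRow(0.0, 2.0)]),
        ],
        {"b": dim},
    )
    return D, dim, structs, plan0
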