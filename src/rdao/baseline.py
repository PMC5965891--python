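"""Two-step comparator: fluence map optimization, then leaf sequencing.

FMO minimizes the same weighted least-squares objective as direct aperture
optimization, but over per-bixel intensities with only a nonnegativity
constraint — a nonnegative least-squares problem, solved exactly by an
active-set method.  The ideal fluence maps are then quantized and decomposed
into deliverable MLC segments (one open interval per leaf row) by a
unidirectional sweep, which reconstructs the quantized map exactly and
achieves the classical minimal total beam-on time

    max_rows sum_c max(0, q[c] - q[c-1]).

The delivered plan's cost can only degrade relative to the ideal fluence
cost; that degradation is what direct aperture optimization avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .dosemodel import (
    Aperture,
    AperturePlan,
    DoseInfluenceMatrix,
    LeafRow,
    plan_dose,
)
from .objective import StructureSet, evaluate_cost

__all__ = [
    "FluenceMap",
    "Segment",
    "FMOResult",
    "BaselineResult",
    "solve_fmo",
    "fluence_dose",
    "sequence_leaves",
    "beam_on_time",
    "reconstruct_quantized",
    "segments_to_apertures",
    "baseline_plan",
]


@dataclass
class FluenceMap:
    """Per-beam nonnegative bixel intensities (n_rows x n_cols)."""

    beam_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("fluence map must be 2-D (rows x columns)")
        if self.values.size and self.values.min() < 0:
            raise ValueError("fluence map entries must be nonnegative")


@dataclass
class Segment:
    """One deliverable MLC shape from sequencing: an interval per row.

    ``intervals`` is an integer (n_rows, 2) array of half-open column ranges
    [start, stop); a closed row has start == stop.  ``units`` is the integer
    number of quantization levels delivered, ``weight`` the physical beam-on
    weight (units x quantization step).
    """

    beam_id: str
    intervals: np.ndarray
    units: int
    weight: float


@dataclass
class FMOResult:
    fluence: dict[str, FluenceMap]
    cost: float
    per_structure: dict[str, float]
    kkt_residual: float


@dataclass
class BaselineResult:
    plan: AperturePlan
    fmo: FMOResult
    segments: dict[str, list[Segment]]
    cost: float
    per_structure: dict[str, float]
    dose: np.ndarray

    @property
    def n_segments(self) -> dict[str, int]:
        return {b: len(segs) for b, segs in self.segments.items()}


def _stacked_system(
    dims: dict[str, DoseInfluenceMatrix], structs: StructureSet
) -> tuple[np.ndarray, np.ndarray, sp.csc_matrix]:
    """Weighted design matrix/targets over scored voxels, and the full DIM."""
    order = list(dims)
    D = sp.hstack([dims[b].values for b in order], format="csc")
    blocks = []
    targets = []
    for s in structs:
        w = np.sqrt(s.weight / s.n_voxels)
        blocks.append(w * np.asarray(D[s.voxel_ids, :].todense()))
        targets.append(np.full(s.n_voxels, w * s.prescription))
    return np.vstack(blocks), np.concatenate(targets), D


def solve_fmo(
    dims: dict[str, DoseInfluenceMatrix],
    structs: StructureSet,
    min_column_mass: float = 0.02,
) -> FMOResult:
    """Ideal fluence maps: weighted NNLS over all beams jointly.

    Bixels whose DIM column deposits less than ``min_column_mass`` of the
    beam's maximum column mass into scored voxels are fixed to zero before
    solving; such grazing columns otherwise attract arbitrarily large
    intensities for negligible dose, which wrecks the subsequent
    quantization.  The remaining problem is solved by the active-set
    nonnegative least-squares method; the reported KKT residual is max over
    optimized bixels of |gradient| on the support and of the negative part
    of the gradient off it, which is ~0 at a true optimum.
    """
    A, b, D = _stacked_system(dims, structs)
    scored = np.unique(np.concatenate([s.voxel_ids for s in structs]))
    active_parts = []
    for bid in dims:
        mass = np.asarray(dims[bid].values[scored, :].sum(axis=0)).ravel()
        top = mass.max()
        active_parts.append(mass >= min_column_mass * top if top > 0 else mass > 0)
    active = np.concatenate(active_parts)

    u = np.zeros(A.shape[1])
    u[active], _ = scipy.optimize.nnls(A[:, active], b)

    g = 2.0 * A[:, active].T @ (A @ u - b)
    on = u[active] > 1e-12
    kkt = max(
        float(np.max(np.abs(g[on]), initial=0.0)),
        float(np.max(np.maximum(0.0, -g[~on]), initial=0.0)),
    )

    dose = D @ u
    cost, per_structure = evaluate_cost(dose, structs)
    fluence: dict[str, FluenceMap] = {}
    off = 0
    for bid in dims:
        g_ = dims[bid].grid
        n = g_.n_bixels
        fluence[bid] = FluenceMap(bid, u[off : off + n].reshape(g_.n_rows, g_.n_cols))
        off += n
    return FMOResult(fluence=fluence, cost=cost, per_structure=per_structure, kkt_residual=kkt)


def fluence_dose(
    fluence: dict[str, FluenceMap], dims: dict[str, DoseInfluenceMatrix]
) -> np.ndarray:
    """Voxel dose delivered by ideal (unsequenced) fluence maps."""
    n_vox = next(iter(dims.values())).n_voxels
    dose = np.zeros(n_vox)
    for bid, fm in fluence.items():
        dose += dims[bid].values @ fm.values.ravel()
    return dose


def sequence_leaves(fm: FluenceMap, n_levels: int = 10) -> list[Segment]:
    """Decompose a fluence map into deliverable interval segments.

    The map is quantized to ``n_levels`` uniform levels (step = max / levels)
    and the integer map is decomposed exactly by the unidirectional sweep: in
    each row, unit level t opens where the running sum of positive gradients
    has reached t and the running sum of negative gradients has not.
    Consecutive identical unit shapes are merged into one weighted segment.
    The weighted sum of segment indicators equals the quantized map
    elementwise, and the total number of units equals the classical minimal
    beam-on time.
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    vals = fm.values
    if vals.size == 0 or vals.max() <= 0:
        return []
    step = vals.max() / n_levels
    q = np.rint(vals / step).astype(np.int64)
    n_rows, n_cols = q.shape

    inc = np.maximum(0, np.diff(q, axis=1, prepend=0))  # rising edges
    dec = np.maximum(0, -np.diff(q, axis=1, prepend=0))  # falling edges
    I = np.cumsum(inc, axis=1)
    Dd = np.cumsum(dec, axis=1)
    total_units = int(I[:, -1].max()) if n_cols else 0

    unit_shapes: list[np.ndarray] = []
    for t in range(1, total_units + 1):
        ivals = np.zeros((n_rows, 2), dtype=np.int64)
        for r in range(n_rows):
            if I[r, -1] < t:
                continue  # row closed for this unit
            left = int(np.argmax(I[r] >= t))
            above = Dd[r] >= t
            right = int(np.argmax(above)) if above.any() else n_cols
            ivals[r] = (left, right)
        unit_shapes.append(ivals)

    segments: list[Segment] = []
    for ivals in unit_shapes:
        if segments and np.array_equal(segments[-1].intervals, ivals):
            last = segments[-1]
            last.units += 1
            last.weight = last.units * step
        else:
            segments.append(Segment(fm.beam_id, ivals, 1, step))
    return segments


def beam_on_time(segments: list[Segment]) -> float:
    """Total beam-on weight of a decomposition (sum of segment weights)."""
    return float(sum(s.weight for s in segments))


def reconstruct_quantized(segments: list[Segment], n_rows: int, n_cols: int) -> np.ndarray:
    """Integer map rebuilt from segment indicators (exactness check)."""
    q = np.zeros((n_rows, n_cols), dtype=np.int64)
    for s in segments:
        for r in range(n_rows):
            a, b = s.intervals[r]
            q[r, a:b] += s.units
    return q


def segments_to_apertures(
    segments: dict[str, list[Segment]], dims: dict[str, DoseInfluenceMatrix]
) -> AperturePlan:
    """Deliverable plan whose apertures are the sequenced segments."""
    aps = [
        Aperture(
            beam_id=bid,
            weight=seg.weight,
            rows=[LeafRow(float(a), float(b)) for a, b in seg.intervals],
        )
        for bid, segs in segments.items()
        for seg in segs
    ]
    return AperturePlan(apertures=aps, dims=dims)


def baseline_plan(
    dims: dict[str, DoseInfluenceMatrix],
    structs: StructureSet,
    n_levels: int = 10,
) -> BaselineResult:
    """Full two-step pipeline: FMO, sequencing, delivered dose and cost."""
    fmo = solve_fmo(dims, structs)
    segments = {bid: sequence_leaves(fm, n_levels) for bid, fm in fmo.fluence.items()}
    plan = segments_to_apertures(segments, dims)
    dose = plan_dose(plan) if plan.apertures else np.zeros(structs.n_voxels)
    cost, per_structure = evaluate_cost(dose, structs)
    return BaselineResult(
        plan=plan,
        fmo=fmo,
        segments=segments,
        cost=cost,
        per_structure=per_structure,
        dose=dose,
    )
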