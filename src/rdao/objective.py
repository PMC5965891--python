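"""Weighted least-squares plan objective and feasibility checks.

The cost of a dose distribution d_calc against per-structure prescriptions is

    F = sum_s (w_s / N_s) * sum_{i in V_s} (d_calc_i - d_i)^2

where V_s is structure s's voxel index set, N_s its size, w_s its importance
weight (weights sum to one) and d_i the prescribed dose (a single scalar per
structure: 1 on targets, 0 on organs at risk).  Voxels may belong to several
structures and are counted in each; unclassified voxels contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosemodel import AperturePlan

__all__ = [
    "Structure",
    "StructureSet",
    "Violation",
    "evaluate_cost",
    "check_feasible",
]

WEIGHT_SUM_TOL = 1e-9


@dataclass
class Structure:
    """A named voxel set with an importance weight and a prescribed dose."""

    name: str
    voxel_ids: np.ndarray
    weight: float
    prescription: float = 0.0

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=np.intp)
        if self.voxel_ids.size == 0:
            raise ValueError(f"structure {self.name!r} has no voxels")
        if self.weight < 0:
            raise ValueError(f"structure {self.name!r} has negative weight {self.weight}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_ids.size)


@dataclass
class StructureSet:
    """All scored structures of a case; weights must sum to unity."""

    structures: list[Structure]
    n_voxels: int

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.structures)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"structure weights sum to {total!r}, expected 1")
        for s in self.structures:
            if s.voxel_ids.max() >= self.n_voxels or s.voxel_ids.min() < 0:
                raise ValueError(f"structure {s.name!r} has voxel ids outside the grid")

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    @property
    def targets(self) -> list[Structure]:
        return [s for s in self.structures if s.prescription > 0]


def evaluate_cost(
    dose: np.ndarray, structs: StructureSet
) -> tuple[float, dict[str, float]]:
    """Total weighted least-squares cost and its per-structure decomposition.

    The per-structure terms sum exactly to the total (the decomposition shown
    as cost bars in plan-comparison reports).
    """
    dose = np.asarray(dose, dtype=float)
    if dose.shape != (structs.n_voxels,):
        raise ValueError(
            f"dose has shape {dose.shape}, expected ({structs.n_voxels},)"
        )
    total_w = sum(s.weight for s in structs.structures)
    if abs(total_w - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"structure weights sum to {total_w!r}, expected 1")

    per_structure: dict[str, float] = {}
    for s in structs:
        resid = dose[s.voxel_ids] - s.prescription
        per_structure[s.name] = (s.weight / s.n_voxels) * float(resid @ resid)
    return sum(per_structure.values()), per_structure


@dataclass(frozen=True)
class Violation:
    """One feasibility defect of a plan, located by aperture and row."""

    aperture: int
    kind: str  # "weight" | "interval" | "range"
    row: int | None
    detail: str


def check_feasible(plan: AperturePlan) -> list[Violation]:
    """Report (never raise) every constraint violation in a plan.

    Checks the nonnegativity of aperture weights, the left<=right leaf
    interval of every row, and leaf positions inside [0, n_cols].
    """
    out: list[Violation] = []
    for k, ap in enumerate(plan.apertures):
        if ap.weight < 0:
            out.append(Violation(k, "weight", None, f"weight {ap.weight} < 0"))
        grid = plan.dims[ap.beam_id].grid if ap.beam_id in plan.dims else None
        for m, row in enumerate(ap.rows):
            if row.x > row.y:
                out.append(
                    Violation(k, "interval", m, f"x={row.x} > y={row.y}")
                )
            if grid is not None and (
                row.x < 0 or row.y > grid.n_cols or row.x > grid.n_cols or row.y < 0
            ):
                out.append(
                    Violation(
                        k, "range", m,
                        f"({row.x}, {row.y}) outside [0, {grid.n_cols}]",
                    )
                )
    return out
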