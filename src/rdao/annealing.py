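"""Modified simulated annealing for direct aperture optimization.

The solver perturbs continuous aperture variables (leaf positions and
aperture weights) with zero-mean Gaussian noise whose width shrinks with the
number of accepted moves,

    sigma(k) = 1 + (L0 - 1) * exp(-log(k + 1) / alpha_cool),

accepts worsening moves with the decreasing probability

    P(k) = 2 * P0 / (1 + exp(log(k + 1) / beta_cool)),

(improving moves are always accepted), and stops each inner sweep when either
``k_succ_max`` acceptances or ``i_max`` iterations are reached.  Temperature
plays no role in the acceptance rule; it only drives the outer schedule: after
each inner sweep the temperature cools geometrically, is re-raised a bounded
number of times once it drops below the reheat threshold ``T_star`` (widening
the search again), and the run ends when it falls below ``T_min`` with all
reheats spent.  A best-state memory guarantees the returned plan is the best
ever visited, not the final one.

Draws that would violate feasibility (negative weight, crossed or
out-of-range leaves) are re-sampled up to a bounded retry count and the
variable is left unchanged if no feasible draw is found, so every state held
by the solver is feasible by construction.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .dosemodel import Aperture, AperturePlan, DoseInfluenceMatrix, LeafRow
from .objective import StructureSet, check_feasible

__all__ = [
    "SAConfig",
    "SAState",
    "SAResult",
    "perturbation_width",
    "acceptance_probability",
    "propose",
    "inner_loop",
    "optimize",
    "initial_plan",
]


@dataclass
class SAConfig:
    """All annealing schedule parameters.

    L0 is the initial Gaussian width in bixel units for leaf moves; weight
    moves use the same schedule scaled by ``weight_move_scale`` since weights
    have no natural grid unit.  ``alpha_cool``/``beta_cool`` are the width and
    acceptance decay rates (named to avoid clashing with aperture weights).
    """

    L0: float = 4.0
    alpha_cool: float = 3.0
    P0: float = 0.3
    beta_cool: float = 3.0
    k_succ_max: int = 100
    i_max: int = 2000
    T_init: float = 1.0
    T_star: float = 0.1
    T_min: float = 0.05
    cool_factor: float = 0.95
    reheat_factor: float = 2.0
    max_reheats: int = 3
    seed: int = 0
    weight_move_scale: float = 0.25
    retry_cap: int = 20
    k_succ_mode: str = "reset"  # "reset" per inner sweep, or "cumulative"
    width_sign: float = -1.0  # exponent sign in the width schedule
    move_scope: str = "variable"  # perturb one "variable" or whole "aperture"
    normalize_in_loop: bool = False  # score D95-normalized dose inside the loop
    restart_from_best: bool = True  # re-anchor the walk at the best state on reheat

    def __post_init__(self) -> None:
        if not self.L0 > 1:
            raise ValueError(f"L0 must exceed 1, got {self.L0}")
        if not (0 < self.P0 <= 0.5):
            raise ValueError(f"P0 must lie in (0, 0.5], got {self.P0}")
        if not (0 < self.T_min <= self.T_star <= self.T_init):
            raise ValueError(
                f"need 0 < T_min <= T_star <= T_init, got "
                f"{self.T_min}, {self.T_star}, {self.T_init}"
            )
        if not (0 < self.cool_factor < 1):
            raise ValueError(f"cool_factor must be in (0,1), got {self.cool_factor}")
        if not self.reheat_factor > 1:
            raise ValueError(f"reheat_factor must exceed 1, got {self.reheat_factor}")
        if self.k_succ_mode not in ("reset", "cumulative"):
            raise ValueError(f"unknown k_succ_mode {self.k_succ_mode!r}")
        if self.move_scope not in ("variable", "aperture"):
            raise ValueError(f"unknown move_scope {self.move_scope!r}")


@dataclass
class SAState:
    """Evolving solver state, with best-state memory and a trace log."""

    current: AperturePlan
    current_cost: float
    best: AperturePlan
    best_cost: float
    temperature: float
    k_succ: int = 0
    i: int = 0
    n_reheats: int = 0
    k_total: int = 0
    iteration: int = 0
    trace: list[tuple] = field(default_factory=list)


@dataclass
class SAResult:
    best_plan: AperturePlan
    best_cost: float
    trace: list[tuple]
    state: SAState

    def trace_frame(self):
        """Trace as a pandas DataFrame (iteration, T, costs, accepted)."""
        import pandas as pd

        return pd.DataFrame(
            self.trace,
            columns=["iteration", "temperature", "current_cost", "best_cost", "accepted"],
        )


def perturbation_width(k_succ: int, cfg: SAConfig) -> float:
    """Gaussian move width after k_succ accepted moves; L0 at 0, -> 1."""
    if k_succ < 0:
        raise ValueError("k_succ must be nonnegative")
    return 1.0 + (cfg.L0 - 1.0) * math.exp(
        cfg.width_sign * math.log(k_succ + 1.0) / cfg.alpha_cool
    )


def acceptance_probability(delta_F: float, k_succ: int, cfg: SAConfig) -> float:
    """Metropolis-style acceptance: 1 for improvements, decaying otherwise."""
    if delta_F < 0:
        return 1.0
    return 2.0 * cfg.P0 / (1.0 + math.exp(math.log(k_succ + 1.0) / cfg.beta_cool))


# ---------------------------------------------------------------------------
# Packed plan representation (hot path)
# ---------------------------------------------------------------------------


class _Packed:
    """Array view of a plan: weights (K,), leaves (K, n_rows_k, 2)."""

    def __init__(self, plan: AperturePlan):
        self.beam_ids = [ap.beam_id for ap in plan.apertures]
        self.weights = np.array([ap.weight for ap in plan.apertures], dtype=float)
        self.leaves = [
            np.array([[r.x, r.y] for r in ap.rows], dtype=float)
            for ap in plan.apertures
        ]
        self.dims = plan.dims

    def copy_aperture(self, k: int) -> tuple[float, np.ndarray]:
        return float(self.weights[k]), self.leaves[k].copy()

    def snapshot(self) -> tuple[np.ndarray, list[np.ndarray]]:
        return self.weights.copy(), [lv.copy() for lv in self.leaves]

    def restore(self, snap: tuple[np.ndarray, list[np.ndarray]]) -> None:
        self.weights = snap[0].copy()
        self.leaves = [lv.copy() for lv in snap[1]]

    def to_plan(self) -> AperturePlan:
        aps = [
            Aperture(
                beam_id=b,
                weight=float(w),
                rows=[LeafRow(float(x), float(y)) for x, y in lv],
            )
            for b, w, lv in zip(self.beam_ids, self.weights, self.leaves)
        ]
        return AperturePlan(apertures=aps, dims=self.dims)


def _perturb_weight(
    weight: float,
    sigma: float,
    w_ref: float,
    cfg: SAConfig,
    rng: np.random.Generator,
) -> float:
    # weights have no natural grid unit: moves scale with the plan's own
    # typical weight so refinement stays possible at any dose scale
    sig_w = sigma * cfg.weight_move_scale * w_ref
    for _ in range(cfg.retry_cap):
        cand = weight + rng.normal(0.0, sig_w)
        if cand >= 0.0:
            return cand
    return weight


def _perturb_row(
    x: float, y: float, n_cols: int, sigma: float, cfg: SAConfig, rng: np.random.Generator
) -> tuple[float, float]:
    for _ in range(cfg.retry_cap):
        dx, dy = rng.normal(0.0, sigma, size=2)
        nx, ny = x + dx, y + dy
        if 0.0 <= nx <= ny <= n_cols:
            return nx, ny
    return x, y


def _perturb_aperture(
    weight: float,
    leaves: np.ndarray,
    n_cols: int,
    sigma: float,
    w_ref: float,
    cfg: SAConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Gaussian-perturb one aperture with feasibility re-sampling.

    ``move_scope="aperture"`` moves the weight and every leaf pair at once;
    ``move_scope="variable"`` moves a single randomly chosen variable (the
    weight, or one leaf pair) -- the finer-grained default.  An infeasible
    draw is re-sampled up to ``cfg.retry_cap`` times, after which that
    variable keeps its previous value, so the result is always feasible.
    """
    new_leaves = leaves.copy()
    if cfg.move_scope == "variable":
        v = int(rng.integers(leaves.shape[0] + 1))
        if v == 0:
            return _perturb_weight(weight, sigma, w_ref, cfg, rng), new_leaves
        m = v - 1
        new_leaves[m] = _perturb_row(*leaves[m], n_cols, sigma, cfg, rng)
        return weight, new_leaves
    new_w = _perturb_weight(weight, sigma, w_ref, cfg, rng)
    for m in range(leaves.shape[0]):
        new_leaves[m] = _perturb_row(*leaves[m], n_cols, sigma, cfg, rng)
    return new_w, new_leaves


def propose(
    state: SAState, cfg: SAConfig, rng: np.random.Generator
) -> AperturePlan:
    """Candidate plan: one randomly chosen aperture Gaussian-perturbed.

    The returned plan is always feasible; with a freshly seeded generator the
    candidate is a deterministic function of the state.
    """
    plan = copy.deepcopy(state.current)
    k = int(rng.integers(len(plan.apertures)))
    ap = plan.apertures[k]
    grid = plan.dims[ap.beam_id].grid
    sigma = perturbation_width(state.k_succ, cfg)
    leaves = np.array([[r.x, r.y] for r in ap.rows], dtype=float)
    w_ref = float(np.mean([a.weight for a in plan.apertures])) or 1.0
    new_w, new_leaves = _perturb_aperture(
        ap.weight, leaves, grid.n_cols, sigma, w_ref, cfg, rng
    )
    ap.weight = new_w
    ap.rows = [LeafRow(float(x), float(y)) for x, y in new_leaves]
    return plan


# ---------------------------------------------------------------------------
# Fast cost evaluator restricted to scored voxels
# ---------------------------------------------------------------------------


class _Evaluator:
    """Dense prefix-sum dose evaluation on the union of scored voxels.

    Only voxels belonging to some structure influence the objective, so the
    per-beam DIM is densified on that subset and prefix-summed along each
    leaf row; one row dose is then two vector subtractions plus at most two
    scaled columns, independent of the opening width.
    """

    def __init__(
        self,
        dims: dict[str, DoseInfluenceMatrix],
        structs: StructureSet,
        normalize: bool = False,
    ):
        vox = np.unique(np.concatenate([s.voxel_ids for s in structs]))
        self.vox = vox
        pos = {v: p for p, v in enumerate(vox)}
        self.struct_idx = [
            np.array([pos[v] for v in s.voxel_ids], dtype=np.intp) for s in structs
        ]
        self.struct_wn = [s.weight / s.n_voxels for s in structs]
        self.struct_d = [s.prescription for s in structs]

        self.normalize = normalize
        self.target_idx = None
        self.target_rx = 1.0
        if normalize:
            targets = structs.targets
            if not targets:
                raise ValueError("in-loop normalization needs a target structure")
            t = targets[0]
            self.target_idx = np.array([pos[v] for v in t.voxel_ids], dtype=np.intp)
            self.target_rx = t.prescription
            # index of the 95%-coverage dose in a descending sort
            self._qk = int(np.ceil(0.95 * t.n_voxels)) - 1

        self.cols: dict[str, np.ndarray] = {}
        self.prefix: dict[str, np.ndarray] = {}
        self.grids = {}
        for bid, dim in dims.items():
            g = dim.grid
            dense = np.asarray(dim.values[vox, :].todense())  # (n_sub, n_bixels)
            dense = dense.reshape(len(vox), g.n_rows, g.n_cols)
            pref = np.zeros((len(vox), g.n_rows, g.n_cols + 1))
            np.cumsum(dense, axis=2, out=pref[:, :, 1:])
            self.cols[bid] = dense
            self.prefix[bid] = pref
            self.grids[bid] = g

    def aperture_unit_dose(self, beam_id: str, leaves: np.ndarray) -> np.ndarray:
        """Unit-weight dose of one aperture on the scored-voxel subset."""
        pref = self.prefix[beam_id]
        cols = self.cols[beam_id]
        dose = np.zeros(pref.shape[0])
        for m in range(leaves.shape[0]):
            x, y = leaves[m]
            if x == y:
                continue
            cx, fy = math.ceil(x), math.floor(y)
            if cx > fy:  # sub-bixel opening
                dose += (y - x) * cols[:, m, math.floor(x)]
                continue
            if fy > cx:
                dose += pref[:, m, fy] - pref[:, m, cx]
            if x != cx:
                dose += (cx - x) * cols[:, m, cx - 1]
            if y != fy:
                dose += (y - fy) * cols[:, m, fy]
        return dose

    def cost(self, dose: np.ndarray) -> float:
        if self.normalize:
            td = dose[self.target_idx]
            q = np.partition(td, len(td) - 1 - self._qk)[len(td) - 1 - self._qk]
            if q > 0:
                dose = dose * (self.target_rx / q)
        total = 0.0
        for idx, wn, d in zip(self.struct_idx, self.struct_wn, self.struct_d):
            r = dose[idx] - d
            total += wn * float(r @ r)
        return total


def _run_inner(
    packed: _Packed,
    evaluator: _Evaluator,
    ap_doses: list[np.ndarray],
    state_dose: np.ndarray,
    state: SAState,
    cfg: SAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One constant-temperature sweep; mutates packed/state, returns dose."""
    if cfg.k_succ_mode == "reset":
        state.k_succ = 0
    state.i = 0
    k_loop = 0  # acceptances this sweep; the stopping counter even when the
    # schedule argument k_succ accumulates across sweeps
    best_snap = None
    while k_loop < cfg.k_succ_max and state.i < cfg.i_max:
        state.i += 1
        state.iteration += 1
        k = int(rng.integers(len(packed.weights)))
        grid = packed.dims[packed.beam_ids[k]].grid
        sigma = perturbation_width(state.k_succ, cfg)
        w_ref = float(packed.weights.mean()) or 1.0
        new_w, new_leaves = _perturb_aperture(
            float(packed.weights[k]), packed.leaves[k], grid.n_cols, sigma, w_ref, cfg, rng
        )
        new_unit = evaluator.aperture_unit_dose(packed.beam_ids[k], new_leaves)
        cand_dose = state_dose - ap_doses[k] + new_w * new_unit
        cand_cost = evaluator.cost(cand_dose)
        delta = cand_cost - state.current_cost
        accepted = rng.uniform() < acceptance_probability(delta, state.k_succ, cfg)
        if accepted:
            packed.weights[k] = new_w
            packed.leaves[k] = new_leaves
            ap_doses[k] = new_w * new_unit
            state_dose = cand_dose
            state.current_cost = cand_cost
            state.k_succ += 1
            state.k_total += 1
            k_loop += 1
            if cand_cost < state.best_cost:
                state.best_cost = cand_cost
                best_snap = packed.snapshot()
        state.trace.append(
            (state.iteration, state.temperature, state.current_cost, state.best_cost, accepted)
        )
    if best_snap is not None:
        bp = _Packed(packed.to_plan())  # cheap container reuse
        bp.restore(best_snap)
        state.best = bp.to_plan()
    return state_dose, best_snap


def inner_loop(
    state: SAState,
    structs: StructureSet,
    cfg: SAConfig,
    rng: np.random.Generator,
) -> SAState:
    """Run one inner sweep on a plan-level state (convenience wrapper)."""
    packed = _Packed(state.current)
    evaluator = _Evaluator(packed.dims, structs, normalize=cfg.normalize_in_loop)
    ap_doses = [
        w * evaluator.aperture_unit_dose(b, lv)
        for b, w, lv in zip(packed.beam_ids, packed.weights, packed.leaves)
    ]
    dose = np.sum(ap_doses, axis=0) if ap_doses else np.zeros(len(evaluator.vox))
    state.current_cost = evaluator.cost(dose)
    if state.best_cost > state.current_cost:
        state.best_cost = state.current_cost
        state.best = copy.deepcopy(state.current)
    _run_inner(packed, evaluator, ap_doses, dose, state, cfg, rng)
    state.current = packed.to_plan()
    return state


def optimize(
    plan0: AperturePlan,
    structs: StructureSet,
    cfg: SAConfig,
) -> SAResult:
    """Anneal a feasible starting plan to a low-cost deliverable plan.

    Outer loop: run an inner sweep, cool the temperature geometrically,
    re-raise it (bounded number of times) once it drops below ``T_star``, and
    stop when it falls below ``T_min`` with reheats exhausted.  Returns the
    best plan ever visited; fully deterministic for a fixed ``cfg.seed``.
    """
    violations = check_feasible(plan0)
    if violations:
        raise ValueError(f"infeasible starting plan: {violations[:3]}")
    plan0.validate()
    if not plan0.apertures:  # nothing to optimize
        evaluator = _Evaluator(plan0.dims, structs, normalize=cfg.normalize_in_loop)
        cost0 = evaluator.cost(np.zeros(len(evaluator.vox)))
        state = SAState(plan0, cost0, plan0, cost0, cfg.T_init)
        return SAResult(plan0, cost0, [], state)

    rng = np.random.default_rng(cfg.seed)
    evaluator = _Evaluator(plan0.dims, structs, normalize=cfg.normalize_in_loop)
    packed = _Packed(plan0)
    ap_doses = [
        w * evaluator.aperture_unit_dose(b, lv)
        for b, w, lv in zip(packed.beam_ids, packed.weights, packed.leaves)
    ]
    dose = np.sum(ap_doses, axis=0) if ap_doses else np.zeros(len(evaluator.vox))
    cost0 = evaluator.cost(dose)

    state = SAState(
        current=plan0,
        current_cost=cost0,
        best=copy.deepcopy(plan0),
        best_cost=cost0,
        temperature=cfg.T_init,
    )
    best_snap = packed.snapshot()
    while not (state.temperature < cfg.T_min and state.n_reheats >= cfg.max_reheats):
        dose, snap = _run_inner(packed, evaluator, ap_doses, dose, state, cfg, rng)
        if snap is not None:
            best_snap = snap
        state.temperature *= cfg.cool_factor
        if state.temperature < cfg.T_star and state.n_reheats < cfg.max_reheats:
            state.temperature *= cfg.reheat_factor
            state.n_reheats += 1
            if cfg.restart_from_best:
                # widen the search again, but around the best plan seen so far
                packed.restore(best_snap)
                ap_doses = [
                    w * evaluator.aperture_unit_dose(b, lv)
                    for b, w, lv in zip(packed.beam_ids, packed.weights, packed.leaves)
                ]
                dose = np.sum(ap_doses, axis=0)
                state.current_cost = evaluator.cost(dose)

    state.current = packed.to_plan()
    return SAResult(
        best_plan=state.best, best_cost=state.best_cost, trace=state.trace, state=state
    )


def initial_plan(
    dims: dict[str, DoseInfluenceMatrix],
    n_apertures: dict[str, int] | int,
    structs: StructureSet | None = None,
    mode: str = "open",
    conformal_threshold: float = 0.1,
) -> AperturePlan:
    """Build a feasible starting plan.

    ``mode="open"`` opens every row fully; ``mode="conformal"`` opens each row
    over the columns whose DIM columns deliver appreciable dose to the target
    (a beam's-eye-view of the target seen through the DIM).  Weights are
    uniform, scaled so the mean target dose matches the prescription when a
    structure set with a target is given, else 1.
    """
    if isinstance(n_apertures, int):
        n_apertures = {bid: n_apertures for bid in dims}
    apertures: list[Aperture] = []
    for bid, dim in dims.items():
        g = dim.grid
        if mode == "open":
            rows = [LeafRow(0.0, float(g.n_cols)) for _ in range(g.n_rows)]
        elif mode == "conformal":
            if structs is None or not structs.targets:
                raise ValueError("conformal initialization needs a target structure")
            tgt = np.concatenate([t.voxel_ids for t in structs.targets])
            sub = np.asarray(dim.values[tgt, :].sum(axis=0)).ravel()
            sub = sub.reshape(g.n_rows, g.n_cols)
            rows = []
            for m in range(g.n_rows):
                prof = sub[m]
                if prof.max() <= 0:
                    rows.append(LeafRow(g.n_cols / 2.0, g.n_cols / 2.0))
                    continue
                open_cols = np.nonzero(prof >= conformal_threshold * prof.max())[0]
                rows.append(LeafRow(float(open_cols.min()), float(open_cols.max() + 1)))
        else:
            raise ValueError(f"unknown initialization mode {mode!r}")
        for _ in range(n_apertures.get(bid, 0)):
            apertures.append(
                Aperture(beam_id=bid, weight=1.0, rows=copy.deepcopy(rows))
            )
    plan = AperturePlan(apertures=apertures, dims=dims)

    if structs is not None and structs.targets:
        from .dosemodel import plan_dose

        tgt_ids = np.concatenate([t.voxel_ids for t in structs.targets])
        rx = float(np.mean([t.prescription for t in structs.targets]))
        unit = plan_dose(plan)[tgt_ids].mean()
        if unit > 0:
            w0 = rx / unit
            for ap in plan.apertures:
                ap.weight = w0
    return plan
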