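# rdao — rapid direct aperture optimization for IMRT

Intensity-modulated radiation therapy is conventionally planned in two
steps: fluence map optimization (FMO) finds ideal per-bixel beam
intensities, and a leaf sequencing algorithm (LSA) then decomposes each
fluence map into apertures deliverable by a multileaf collimator (MLC).
Sequencing degrades the plan: the delivered fluence is a quantized,
interval-constrained approximation of the ideal one.  Direct aperture
optimization (DAO) avoids the decomposition by optimizing the deliverable
variables themselves — per-aperture beam-on weights α_k and continuous
left/right leaf positions (x_km, y_km) for every leaf row m.

This package implements a *rapid* DAO: dose is evaluated not by Monte Carlo
but through a precomputed dose influence matrix (DIM) D_ij — dose to voxel i
per unit fluence through bixel j — extended to continuous leaf positions by
a piecewise-linear aperture dose model: bixels fully inside the opening
contribute their full DIM column, the boundary bixels contribute in
proportion to their covered fraction.  The plan objective is the weighted
least-squares cost

    F(α, x, y) = Σ_s (w_s / N_s) Σ_{i ∈ V_s} ( Σ_{(k,m)} α_k f_ikm(x_km, y_km) − d_i )²,

minimized over α ≥ 0 and feasible leaf intervals by a modified simulated
annealer: Gaussian moves whose width shrinks with the number of accepted
moves, σ(k) = 1 + (L0 − 1)·exp(−log(k+1)/α_cool); Metropolis acceptance
with a decaying probability 2·P0 / (1 + exp(log(k+1)/β_cool)) for worsening
moves; dual inner stopping thresholds (k_succ / i_max); a best-state memory;
and an outer temperature schedule with bounded reheating.  The classical
FMO→LSA pipeline (nonnegative least squares + exact sweep sequencing) is
included as the comparator, and a synthetic phantom generator (C-shaped
target wrapping a core organ at risk, and two other presets) makes every
experiment self-contained and deterministic.

Intended users: medical-physics researchers studying plan-optimization
algorithms at desk scale, and anyone needing a clean, tested reference
implementation of DIM-based aperture dose modeling, Engel-style sweep
sequencing, or memory-SA with reheating.

## Worked example

```python
import rdao

case = rdao.make_case("c_shape", grid_shape=(24, 24, 12))
report, sa, base = rdao.run_case_comparison(case, seed=0)

print(f"ideal fluence cost      {base.fmo.cost:.5f}")
print(f"sequenced (FMO-LSA)     {report.total_cost['fmo_lsa']:.5f}")
print(f"direct (RDAO)           {report.total_cost['rdao']:.5f}")
print(f"PTV cost change         {report.relative_change['ptv']:+.1%}")
print(f"core OAR cost change    {report.relative_change['core']:+.1%}")
```

prints (about 25 s on one CPU):

```
ideal fluence cost      0.00391
sequenced (FMO-LSA)     0.00687
direct (RDAO)           0.00620
PTV cost change         +17.8%
core OAR cost change    +1.2%
```

Reading: the ideal fluence plan costs 0.00391 but is not deliverable;
sequencing it into 28 MLC segments raises the cost to 0.00687 (both doses
rescaled so 95% of the target receives the prescription).  Direct
optimization of the same 28 apertures — continuous leaf refinement under
the annealer — recovers a 9.8% lower total cost, with most of the gain in
target-dose homogeneity (PTV term −17.8%) at essentially unchanged
organ-at-risk dose.  Positive relative changes mean the direct plan
improves on the two-step baseline.

A CLI wraps the same workflow (`rdao generate`, `rdao rdao`, `rdao
fmo-lsa`, `rdao dose`, `rdao compare`); all artifacts are plain text
(MatrixMarket DIMs, JSON plans/manifests, CSV traces and DVHs).

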