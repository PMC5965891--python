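"""Plain-text on-disk formats for cases, plans and results.

Dose influence matrices are stored one MatrixMarket coordinate file per beam
next to a JSON sidecar with the grid geometry and beam angles; structure
sets, plans and manifests are JSON; fluence maps, segments, traces and DVH
curves are whitespace/CSV text.  Everything round-trips exactly enough for
regeneration tests (sparse values via MatrixMarket's full-precision floats).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .baseline import FluenceMap, Segment
from .dosemodel import Aperture, AperturePlan, BixelGrid, DoseInfluenceMatrix, LeafRow
from .objective import Structure, StructureSet

__all__ = [
    "save_dim",
    "load_dim",
    "save_case",
    "load_case",
    "save_structures",
    "load_structures",
    "save_plan",
    "load_plan",
    "save_fluence",
    "load_fluence",
    "save_segments",
    "save_trace",
    "save_dvh",
]


def save_dim(dim: DoseInfluenceMatrix, path: Path | str, sidecar: dict | None = None) -> None:
    """Write one beam's DIM as .mtx plus a JSON geometry sidecar."""
    path = Path(path)
    scipy.io.mmwrite(str(path), sp.coo_matrix(dim.values))
    meta = {
        "beam_id": dim.grid.beam_id,
        "n_rows": dim.grid.n_rows,
        "n_cols": dim.grid.n_cols,
        "bixel_width": dim.grid.bixel_width,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_dim(path: Path | str) -> DoseInfluenceMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = BixelGrid(
        beam_id=meta["beam_id"],
        n_rows=meta["n_rows"],
        n_cols=meta["n_cols"],
        bixel_width=meta["bixel_width"],
    )
    values = scipy.io.mmread(str(path if path.suffix else path.with_suffix(".mtx")))
    return DoseInfluenceMatrix(grid, values)


def save_structures(structs: StructureSet, path: Path | str) -> None:
    payload = {
        "n_voxels": structs.n_voxels,
        "structures": [
            {
                "name": s.name,
                "weight": s.weight,
                "prescription": s.prescription,
                "voxel_ids": s.voxel_ids.tolist(),
            }
            for s in structs
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_structures(path: Path | str) -> StructureSet:
    payload = json.loads(Path(path).read_text())
    return StructureSet(
        structures=[
            Structure(
                name=s["name"],
                voxel_ids=np.asarray(s["voxel_ids"], dtype=np.intp),
                weight=s["weight"],
                prescription=s["prescription"],
            )
            for s in payload["structures"]
        ],
        n_voxels=payload["n_voxels"],
    )


def save_case(case, out_dir: Path | str) -> None:
    """Write a synthetic case: per-beam DIMs, structures and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for bid, dim in case.dims.items():
        save_dim(dim, out / f"dim_{bid}.mtx")
    save_structures(case.structs, out / "structures.json")
    (out / "manifest.json").write_text(json.dumps(case.manifest, indent=1))


def load_case(case_dir: Path | str):
    """Load DIMs and structures written by :func:`save_case`."""
    case_dir = Path(case_dir)
    dims = {}
    for mtx in sorted(case_dir.glob("dim_*.mtx")):
        dim = load_dim(mtx)
        dims[dim.grid.beam_id] = dim
    structs = load_structures(case_dir / "structures.json")
    manifest_path = case_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return dims, structs, manifest


def save_plan(plan: AperturePlan, path: Path | str) -> None:
    payload = [
        {
            "beam_id": ap.beam_id,
            "weight": ap.weight,
            "rows": [[r.x, r.y] for r in ap.rows],
        }
        for ap in plan.apertures
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_plan(path: Path | str, dims: dict[str, DoseInfluenceMatrix]) -> AperturePlan:
    payload = json.loads(Path(path).read_text())
    apertures = [
        Aperture(
            beam_id=ap["beam_id"],
            weight=ap["weight"],
            rows=[LeafRow(x, y) for x, y in ap["rows"]],
        )
        for ap in payload
    ]
    return AperturePlan(apertures=apertures, dims=dims)


def save_fluence(fm: FluenceMap, path: Path | str) -> None:
    np.savetxt(path, fm.values, header=f"beam_id {fm.beam_id}")


def load_fluence(path: Path | str) -> FluenceMap:
    path = Path(path)
    beam_id = path.read_text().splitlines()[0].split()[-1]
    return FluenceMap(beam_id, np.atleast_2d(np.loadtxt(path)))


def save_segments(segments: dict[str, list[Segment]], path: Path | str) -> None:
    """Segments as CSV: beam, segment, row, start, end, weight."""
    lines = ["beam,segment,row,start,end,weight"]
    for bid, segs in segments.items():
        for t, seg in enumerate(segs):
            for r, (a, b) in enumerate(seg.intervals):
                lines.append(f"{bid},{t},{r},{a},{b},{seg.weight:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_trace(trace: list[tuple], path: Path | str) -> None:
    """Annealing trace as CSV (iteration, temperature, costs, accepted)."""
    lines = ["iteration,temperature,current_cost,best_cost,accepted"]
    for it, T, cur, best, acc in trace:
        lines.append(f"{it},{T:.12g},{cur:.12g},{best:.12g},{int(acc)}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_dvh(curves: dict[str, "object"], path: Path | str) -> None:
    """DVH curves as long-format CSV (structure, dose, volume_fraction)."""
    lines = ["structure,dose,volume_fraction"]
    for name, curve in curves.items():
        for d, v in zip(curve.dose_edges, curve.volume_fraction):
            lines.append(f"{name},{d:.10g},{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
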