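"""Desk-scale synthetic phantoms, beams and dose influence matrices.

Generates small fully deterministic test cases shaped like a real planning
problem: a 3-D voxel grid with a target (PTV) and organ-at-risk (OAR) masks,
several beams each carrying an MLC bixel grid, and one sparse nonnegative
dose influence matrix per beam.  The dose physics is deliberately minimal —
parallel-ray geometry with exponential depth attenuation and a Gaussian
lateral penumbra integrated over each bixel — because the point of the
artifact is optimization machinery, not dose engines.

Presets
-------
``c_shape``        C-shaped target wrapping a central cylindrical core OAR
                   (the classical commissioning geometry).
``prostate_like``  Central ellipsoidal target with two flanking OARs.
``two_oar``        Spherical target flanked by two spherical OARs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .dosemodel import BixelGrid, DoseInfluenceMatrix
from .objective import Structure, StructureSet

__all__ = [
    "Phantom",
    "BeamSpec",
    "make_phantom",
    "compute_dim",
    "make_case",
    "default_beams",
    "PRESETS",
]

PRESETS = ("c_shape", "prostate_like", "two_oar")


@dataclass
class Phantom:
    grid_shape: tuple[int, int, int]
    voxel_size: float
    ptv_mask: np.ndarray
    oar_masks: dict[str, np.ndarray]
    density: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass(frozen=True)
class BeamSpec:
    """One beam: direction angles plus its MLC bixel grid geometry."""

    gantry_angle: float
    couch_angle: float = 0.0
    n_rows: int = 6
    n_cols: int = 10
    bixel_width: float = 2.0
    leaf_width: float = 2.0
    attenuation: float = 0.05  # per length unit along the ray
    penumbra_sigma: float = 0.8  # lateral Gaussian width, length units

    def __post_init__(self) -> None:
        if not (0 <= self.gantry_angle < 360):
            raise ValueError(f"gantry angle {self.gantry_angle} outside [0, 360)")
        if not (-90 <= self.couch_angle <= 90):
            raise ValueError(f"couch angle {self.couch_angle} outside [-90, 90]")

    @property
    def beam_id(self) -> str:
        return f"g{self.gantry_angle:g}c{self.couch_angle:g}"

    def direction(self) -> np.ndarray:
        """Unit vector from source toward isocenter."""
        g = math.radians(self.gantry_angle)
        k = math.radians(self.couch_angle)
        b0 = np.array([-math.sin(g), math.cos(g), 0.0])
        ck, sk = math.cos(k), math.sin(k)
        return np.array([b0[0] * ck + b0[2] * sk, b0[1], -b0[0] * sk + b0[2] * ck])


def _grid_coords(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Voxel-center coordinates, isocenter at the grid center; (n_vox, 3)."""
    axes = [ (np.arange(n) - (n - 1) / 2.0) * voxel_size for n in shape ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def make_phantom(
    preset: str,
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Deterministic phantom with non-overlapping PTV and OAR masks."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    nx, ny, nz = grid_shape
    coords = _grid_coords(grid_shape, voxel_size).reshape(nx, ny, nz, 3)
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    extent = min(nx, ny) * voxel_size / 2.0
    zlen = nz * voxel_size / 2.0
    in_z = np.abs(z) <= 0.5 * zlen

    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    if preset == "c_shape":
        core_r = 0.15 * extent
        r_in, r_out = 0.30 * extent, 0.55 * extent
        gap = np.abs(theta) < math.radians(50)  # opening of the C toward +x
        ptv = (r >= r_in) & (r <= r_out) & ~gap & in_z
        core = (r <= core_r) & in_z
        oars = {"core": core}
    elif preset == "prostate_like":
        ptv = ((x / (0.25 * extent)) ** 2 + (y / (0.2 * extent)) ** 2
               + (z / (0.45 * zlen)) ** 2) <= 1.0
        oar1 = (np.hypot(x, y - 0.45 * extent) <= 0.15 * extent) & in_z
        oar2 = ((x / (0.2 * extent)) ** 2 + ((y + 0.5 * extent) / (0.22 * extent)) ** 2
                + (z / (0.45 * zlen)) ** 2) <= 1.0
        ptv &= ~(oar1 | oar2)
        oars = {"oar_posterior": oar1, "oar_anterior": oar2}
    else:  # two_oar
        rad = 0.25 * extent
        ptv = (x**2 + y**2 + (z * extent / zlen * 0.7) ** 2) <= rad**2
        oar1 = ((x - 0.55 * extent) ** 2 + y**2 + z**2) <= (0.18 * extent) ** 2
        oar2 = ((x + 0.55 * extent) ** 2 + y**2 + z**2) <= (0.18 * extent) ** 2
        ptv &= ~(oar1 | oar2)
        oars = {"oar_right": oar1, "oar_left": oar2}

    for name, mask in oars.items():
        overlap = mask & ptv
        if overlap.any():
            oars[name] = mask & ~ptv
    if not ptv.any():
        raise ValueError("degenerate phantom: empty target")
    return Phantom(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        ptv_mask=ptv,
        oar_masks=oars,
        density=np.ones(grid_shape),
    )


def compute_dim(
    phantom: Phantom,
    beam: BeamSpec,
    drop_fraction: float = 1e-3,
) -> DoseInfluenceMatrix:
    """Ray-traced dose influence matrix for one beam.

    Each bixel deposits dose exp(-mu * depth) times the Gaussian-penumbra
    kernel integrated across the bixel opening in both lateral directions.
    Per column, the smallest entries whose combined mass stays below
    ``drop_fraction`` of the column total are dropped to keep the matrix
    sparse.
    """
    grid = BixelGrid(
        beam_id=beam.beam_id,
        n_rows=beam.n_rows,
        n_cols=beam.n_cols,
        bixel_width=beam.bixel_width,
    )
    coords = _grid_coords(phantom.grid_shape, phantom.voxel_size)
    b = beam.direction()
    v0 = np.array([0.0, 0.0, 1.0])
    u = np.cross(v0, b)
    if np.linalg.norm(u) < 1e-9:  # beam along the patient axis
        u = np.array([1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(b, u)

    depth = coords @ b
    depth -= depth.min()
    att = np.exp(-beam.attenuation * depth) * phantom.density.ravel()

    ucoord = coords @ u
    vcoord = coords @ v
    s = beam.penumbra_sigma * math.sqrt(2.0)

    def edge_integrals(lat: np.ndarray, n: int, width: float) -> np.ndarray:
        """Integrated Gaussian across each of n strips; (n_vox, n)."""
        edges = (np.arange(n + 1) - n / 2.0) * width
        from scipy.special import erf

        E = erf((lat[:, None] - edges[None, :]) / s)
        return 0.5 * (E[:, :-1] - E[:, 1:])  # = Phi(right edge) - Phi(left edge)

    Eu = edge_integrals(ucoord, beam.n_cols, beam.bixel_width)
    Ev = edge_integrals(vcoord, beam.n_rows, beam.leaf_width)

    n_vox = phantom.n_voxels
    cols_data, cols_idx, indptr = [], [], [0]
    for m in range(beam.n_rows):
        base = att * Ev[:, m]
        for c in range(beam.n_cols):
            col = base * Eu[:, c]
            col[col < 0] = 0.0
            total = col.sum()
            if total <= 0:
                indptr.append(indptr[-1])
                continue
            order = np.argsort(col)
            csum = np.cumsum(col[order])
            keep_from = int(np.searchsorted(csum, drop_fraction * total, side="left"))
            kept = np.sort(order[keep_from:])
            kept = kept[col[kept] > 0]
            cols_idx.append(kept)
            cols_data.append(col[kept])
            indptr.append(indptr[-1] + len(kept))
    data = np.concatenate(cols_data) if cols_data else np.empty(0)
    idx = np.concatenate(cols_idx) if cols_idx else np.empty(0, dtype=np.intp)
    values = sp.csc_matrix(
        (data, idx, np.asarray(indptr)), shape=(n_vox, grid.n_bixels)
    )
    if values.nnz == 0:
        import warnings

        warnings.warn(f"beam {beam.beam_id} misses the grid entirely", stacklevel=2)
    return DoseInfluenceMatrix(grid, values)


def default_beams(n_beams: int = 5, **kwargs) -> list[BeamSpec]:
    """Equally spaced coplanar beams starting at gantry 0."""
    return [BeamSpec(gantry_angle=360.0 * i / n_beams, **kwargs) for i in range(n_beams)]


@dataclass
class Case:
    """A complete synthetic planning case plus its regeneration manifest."""

    phantom: Phantom
    dims: dict[str, DoseInfluenceMatrix]
    structs: StructureSet
    manifest: dict = field(default_factory=dict)


def make_case(
    preset: str = "c_shape",
    beams: list[BeamSpec] | None = None,
    weights: dict[str, float] | None = None,
    prescriptions: dict[str, float] | None = None,
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size: float = 1.0,
    seed: int = 0,
) -> Case:
    """Bundle phantom, per-beam DIMs and structure set for one case.

    Default weights put 0.9 on the target and split 0.1 over the OARs;
    prescriptions default to 1 on the target and 0 on OARs.  The manifest
    records every parameter so the case regenerates bit-identically.
    """
    if beams is None:
        beams = default_beams()
    if not beams:
        raise ValueError("a case needs at least one beam")
    phantom = make_phantom(preset, grid_shape, voxel_size, seed)

    names = ["ptv"] + list(phantom.oar_masks)
    if weights is None:
        n_oar = len(phantom.oar_masks)
        weights = {"ptv": 0.9, **{n: 0.1 / n_oar for n in phantom.oar_masks}}
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError(f"structure weights must sum to 1, got {sum(weights.values())}")
    if prescriptions is None:
        prescriptions = {"ptv": 1.0, **{n: 0.0 for n in phantom.oar_masks}}

    masks = {"ptv": phantom.ptv_mask, **phantom.oar_masks}
    structures = [
        Structure(
            name=n,
            voxel_ids=np.flatnonzero(masks[n].ravel()),
            weight=weights[n],
            prescription=prescriptions[n],
        )
        for n in names
    ]
    structs = StructureSet(structures=structures, n_voxels=phantom.n_voxels)
    dims = {b.beam_id: compute_dim(phantom, b) for b in beams}

    manifest = {
        "preset": preset,
        "grid_shape": list(grid_shape),
        "voxel_size": voxel_size,
        "seed": seed,
        "weights": weights,
        "prescriptions": prescriptions,
        "beams": [
            {
                "gantry_angle": b.gantry_angle,
                "couch_angle": b.couch_angle,
                "n_rows": b.n_rows,
                "n_cols": b.n_cols,
                "bixel_width": b.bixel_width,
                "leaf_width": b.leaf_width,
                "attenuation": b.attenuation,
                "penumbra_sigma": b.penumbra_sigma,
            }
            for b in beams
        ],
    }
    return Case(phantom=phantom, dims=dims, structs=structs, manifest=manifest)
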