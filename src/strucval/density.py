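"""Model-versus-data fit: density maps, per-residue RSR, RSRZ, LLDF, R factors.

The observed map may come from a CCP4/MRC file or from the synthetic-fixture
path (an analytically computed model map plus seeded noise). The fit measures
follow the real-space R convention: RSR = sum|rho_obs - rho_calc| /
sum(|rho_obs| + |rho_calc|) over a mask of grid points near the residue.
RSR is normalized per residue type and resolution band into RSRZ (one-sided
outlier rule at 2). Ligands and other non-standard entities get the local
ligand density fit (LLDF): a Z score of the ligand's RSR against the RSRs of
standard residues within 5.0 A, undefined with fewer than two neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .model import Residue, ResidueKind, StructureModel, UnitCell, symmetry_images
from .refdata import ArchiveStats

__all__ = [
    "DensityMap",
    "ResidueFit",
    "LigandFit",
    "ReflectionSet",
    "read_ccp4_map",
    "write_ccp4_map",
    "synthesize_map",
    "residue_rsr",
    "residue_fits",
    "rsrz",
    "lldf",
    "find_ligand_neighbors",
    "r_factors",
    "read_reflections",
    "MASK_RADIUS",
    "RSRZ_OUTLIER",
    "LLDF_HIGHLIGHT",
    "NEIGHBOR_RADIUS",
]

MASK_RADIUS = 1.8       # A around heavy atoms
RSRZ_OUTLIER = 2.0      # one-sided
LLDF_HIGHLIGHT = 2.0    # one-sided
NEIGHBOR_RADIUS = 5.0   # A, LLDF neighborhood


@dataclass
class DensityMap:
    """Real scalar density on a regular grid over a (possibly triclinic) cell.

    Grid point (0,0,0) sits at fractional (0,0,0); point (i,j,k) at
    fractional (i/nx, j/ny, k/nz)."""

    values: np.ndarray  # (nx, ny, nz)
    cell: UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3D with dims >= 2")
        if not np.isfinite(self.values).all():
            raise ValueError("density grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(),
                          UnitCell(self.cell.a, self.cell.b, self.cell.c,
                                   self.cell.alpha, self.cell.beta, self.cell.gamma))


def read_ccp4_map(path: str) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True)
    c = m.grid.unit_cell
    return DensityMap(arr, UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))


def write_ccp4_map(dmap: DensityMap, path: str) -> None:
    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(dmap.cell.to_gemmi())
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# analytic model map

def _gaussian_width(b_iso: float, min_b: float = 5.0) -> float:
    """Isotropic Gaussian sigma (A) from the B factor: sigma^2 = B / (8 pi^2)."""
    return math.sqrt(max(b_iso, min_b) / (8.0 * math.pi ** 2))


def synthesize_map(structure: StructureModel, spacing: float = 0.5,
                   include_hydrogens: bool = False, cutoff_sigmas: float = 5.0) -> DensityMap:
    """Model density as a sum of normalized atomic Gaussians.

    Each atom contributes amplitude Z * occupancy with width set by its B
    factor, so the map integral of an isolated atom equals Z * occupancy.
    The grid wraps periodically over the cell."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    atoms = structure.all_atoms(include_hydrogens=include_hydrogens)
    if not atoms:
        raise ValueError("cannot synthesize a map for an empty structure")
    cell = structure.ensure_cell()
    dims = tuple(max(2, int(math.ceil(L / spacing))) for L in (cell.a, cell.b, cell.c))
    values = np.zeros(dims)
    _add_atoms(values, cell, atoms, cutoff_sigmas)
    return DensityMap(values, cell)


def _add_atoms(values: np.ndarray, cell: UnitCell, atoms, cutoff_sigmas: float) -> None:
    nx, ny, nz = values.shape
    orth = cell.orth_matrix()
    frac = cell.frac_matrix()
    steps = np.array([1.0 / nx, 1.0 / ny, 1.0 / nz])
    # approximate Cartesian grid step per axis for box sizing
    axis_len = np.array([np.linalg.norm(orth[:, i]) for i in range(3)])
    for res, atom in atoms:
        z = gemmi.Element(atom.element).atomic_number or 6
        sigma = _gaussian_width(atom.b_iso)
        amp = z * atom.occupancy / ((2.0 * math.pi * sigma * sigma) ** 1.5)
        cutoff = cutoff_sigmas * sigma
        fcen = frac @ atom.pos
        half = np.ceil(cutoff / (axis_len * steps)).astype(int) + 1
        i0 = np.floor(fcen / steps).astype(int)
        ii = np.arange(i0[0] - half[0], i0[0] + half[0] + 1)
        jj = np.arange(i0[1] - half[1], i0[1] + half[1] + 1)
        kk = np.arange(i0[2] - half[2], i0[2] + half[2] + 1)
        fi, fj, fk = np.meshgrid(ii * steps[0], jj * steps[1], kk * steps[2], indexing="ij")
        pts = np.stack([fi, fj, fk], axis=-1) @ orth.T
        d2 = ((pts - atom.pos) ** 2).sum(axis=-1)
        contrib = amp * np.exp(-0.5 * d2 / (sigma * sigma))
        contrib[d2 > cutoff * cutoff] = 0.0
        np.add.at(values, (np.ix_(ii % nx, jj % ny, kk % nz)), contrib)


# ---------------------------------------------------------------------------
# masks and RSR

def mask_indices(coords: np.ndarray, dmap: DensityMap, mask_radius: float = MASK_RADIUS) -> np.ndarray:
    """Boolean grid mask of points within mask_radius of any coordinate,
    with periodic wrapping."""
    nx, ny, nz = dmap.shape
    mask = np.zeros(dmap.shape, dtype=bool)
    orth = dmap.cell.orth_matrix()
    frac = dmap.cell.frac_matrix()
    steps = np.array([1.0 / nx, 1.0 / ny, 1.0 / nz])
    axis_len = np.array([np.linalg.norm(orth[:, i]) for i in range(3)])
    for pos in np.atleast_2d(coords):
        fcen = frac @ pos
        half = np.ceil(mask_radius / (axis_len * steps)).astype(int) + 1
        i0 = np.floor(fcen / steps).astype(int)
        ii = np.arange(i0[0] - half[0], i0[0] + half[0] + 1)
        jj = np.arange(i0[1] - half[1], i0[1] + half[1] + 1)
        kk = np.arange(i0[2] - half[2], i0[2] + half[2] + 1)
        fi, fj, fk = np.meshgrid(ii * steps[0], jj * steps[1], kk * steps[2], indexing="ij")
        pts = np.stack([fi, fj, fk], axis=-1) @ orth.T
        d2 = ((pts - pos) ** 2).sum(axis=-1)
        sel = d2 <= mask_radius * mask_radius
        if sel.any():
            idx = np.ix_(ii % nx, jj % ny, kk % nz)
            mask[idx] |= sel
    return mask


def residue_rsr(residue: Residue, map_obs: DensityMap, map_calc: DensityMap,
                mask_radius: float = MASK_RADIUS) -> Optional[float]:
    """Real-space R over grid points near the residue's heavy atoms.

    None when the mask is empty or both maps vanish on it."""
    if map_obs.shape != map_calc.shape:
        raise ValueError("observed and calculated maps must share a grid")
    coords = residue.heavy_coords()
    if coords.shape[0] == 0:
        return None
    mask = mask_indices(coords, map_obs, mask_radius)
    if not mask.any():
        return None
    a = map_obs.values[mask]
    b = map_calc.values[mask]
    denom = float(np.abs(a).sum() + np.abs(b).sum())
    if denom == 0.0:
        return None
    return float(np.abs(a - b).sum() / denom)


@dataclass
class ResidueFit:
    rsr: Optional[float]
    rsrz: Optional[float] = None
    outlier: bool = False


@dataclass
class LigandFit:
    rsr: Optional[float]
    n_neighbors: int
    lldf: Optional[float]
    highlighted: bool
    reason: Optional[str] = None


def rsrz(rsr: float, res_type: str, resolution: float,
         stats: ArchiveStats) -> tuple[Optional[float], bool]:
    """Normalize an RSR by residue type and resolution band.

    Returns (rsrz, outlier); rsrz is None when the archive lacks the band."""
    band = stats.rsr_band(res_type, resolution)
    if band is None:
        return None, False
    mean, sd = band
    z = (rsr - mean) / sd
    return z, z > RSRZ_OUTLIER


def residue_fits(structure: StructureModel, map_obs: DensityMap, map_calc: DensityMap,
                 stats: Optional[ArchiveStats] = None,
                 mask_radius: float = MASK_RADIUS) -> dict[tuple[str, int, str], ResidueFit]:
    """Per-residue RSR (and RSRZ when archive statistics are available)."""
    fits: dict[tuple[str, int, str], ResidueFit] = {}
    for res in structure.residues():
        r = residue_rsr(res, map_obs, map_calc, mask_radius)
        fit = ResidueFit(rsr=r)
        if (r is not None and stats is not None and structure.resolution is not None
                and res.kind in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT)):
            fit.rsrz, fit.outlier = rsrz(r, res.name, structure.resolution, stats)
        fits[res.key] = fit
    return fits


# ---------------------------------------------------------------------------
# LLDF

def find_ligand_neighbors(ligand: Residue, structure: StructureModel,
                          radius: float = NEIGHBOR_RADIUS) -> list[tuple[str, int, str]]:
    """Standard residues with any heavy atom within `radius` of any heavy
    ligand atom, crystallographic symmetry images included when a real cell
    is present."""
    lig_coords = ligand.heavy_coords()
    if lig_coords.shape[0] == 0:
        return []
    from scipy.spatial import cKDTree

    lig_tree = cKDTree(lig_coords)
    neighbors: set[tuple[str, int, str]] = set()
    for res in structure.residues():
        if res.key == ligand.key:
            continue
        if res.kind not in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT):
            continue
        coords = res.heavy_coords()
        if coords.shape[0] and lig_tree.query(coords, k=1)[0].min() <= radius:
            neighbors.add(res.key)
    if structure.cell is not None and not structure.cell_is_placeholder:
        # images of standard residues near the AU; test proximity to the ligand
        for res, atom, image, op, shift in symmetry_images(structure, radius):
            if res.kind not in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT):
                continue
            if res.key == ligand.key or image.is_hydrogen:
                continue
            if lig_tree.query(image.pos, k=1)[0] <= radius:
                neighbors.add(res.key)
    return sorted(neighbors)


def lldf(ligand: Residue,
         residue_rsr_table: dict[tuple[str, int, str], float],
         structure: StructureModel,
         ligand_rsr: Optional[float] = None,
         radius: float = NEIGHBOR_RADIUS,
         highlight: float = LLDF_HIGHLIGHT) -> LigandFit:
    """Local ligand density fit.

    Neighbors are the standard residues within 5.0 A of the ligand; the
    ligand's RSR is standardized against the sample mean/SD (ddof=1) of the
    neighbors' RSR values. Fewer than two neighbors, or a degenerate (zero
    SD) neighborhood, leaves LLDF undefined."""
    neighbor_keys = find_ligand_neighbors(ligand, structure, radius)
    rsr_vals = [residue_rsr_table[k] for k in neighbor_keys
                if residue_rsr_table.get(k) is not None]
    if ligand_rsr is None:
        ligand_rsr = residue_rsr_table.get(ligand.key)
    n = len(rsr_vals)
    if n < 2:
        return LigandFit(rsr=ligand_rsr, n_neighbors=n, lldf=None,
                         highlighted=False, reason="fewer than two neighbors")
    if ligand_rsr is None:
        return LigandFit(rsr=None, n_neighbors=n, lldf=None,
                         highlighted=False, reason="ligand RSR unavailable")
    arr = np.asarray(rsr_vals)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return LigandFit(rsr=ligand_rsr, n_neighbors=n, lldf=None,
                         highlighted=False, reason="degenerate neighborhood")
    z = (ligand_rsr - float(arr.mean())) / sd
    return LigandFit(rsr=ligand_rsr, n_neighbors=n, lldf=z, highlighted=z > highlight)


# ---------------------------------------------------------------------------
# reflections and R factors

@dataclass
class ReflectionSet:
    h: np.ndarray
    k: np.ndarray
    l: np.ndarray
    f_obs: np.ndarray
    f_calc: np.ndarray
    free: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        self.f_calc = np.asarray(self.f_calc, dtype=float)
        self.free = np.asarray(self.free, dtype=bool)
        if (self.f_obs < 0).any() or (self.f_calc < 0).any():
            raise ValueError("structure-factor amplitudes must be non-negative")

    @property
    def free_fraction(self) -> float:
        return float(self.free.mean()) if self.free.size else 0.0


def read_reflections(path: str) -> ReflectionSet:
    """Reflection CSV with columns h,k,l,fobs,fcalc,free."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("h", "k", "l", "fobs", "fcalc", "free"):
        if need not in cols:
            raise ValueError(f"reflection file missing column '{need}'")
    return ReflectionSet(
        h=df[cols["h"]].to_numpy(int), k=df[cols["k"]].to_numpy(int),
        l=df[cols["l"]].to_numpy(int),
        f_obs=df[cols["fobs"]].to_numpy(float),
        f_calc=df[cols["fcalc"]].to_numpy(float),
        free=df[cols["free"]].to_numpy().astype(bool),
    )


def r_factors(refl: ReflectionSet) -> tuple[Optional[float], Optional[float]]:
    """(R_work, R_free) with the linear scale fit on the work set only.

    R = sum| |Fobs| - k |Fcalc| | / sum |Fobs|, k = sum FoFc / sum Fc^2."""
    work = ~refl.free
    free = refl.free

    def r_of(sel: np.ndarray, scale: float) -> Optional[float]:
        fo, fc = refl.f_obs[sel], refl.f_calc[sel]
        denom = fo.sum()
        if fo.size == 0 or denom == 0:
            return None
        return float(np.abs(fo - scale * fc).sum() / denom)

    fc2 = (refl.f_calc[work] ** 2).sum()
    if work.sum() == 0 or fc2 == 0:
        return None, None
    scale = float((refl.f_obs[work] * refl.f_calc[work]).sum() / fc2)
    return r_of(work, scale), r_of(free, scale)
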