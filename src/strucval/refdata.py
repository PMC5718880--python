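"""Reference bundles: everything the validators compare a model against.

A ReferenceBundle aggregates six reference types — covalent geometry targets,
Ramachandran frequency grids, a rotamer library, small-molecule fragment
statistics, archive-wide metric distributions, and chemical-shift statistics —
plus auxiliary tables (van der Waals radii, chirality expectations, expected
atoms per residue). The validation engine is agnostic to where a bundle's
numbers come from; the packaged default is generated from documented analytic
families so that ideal fixtures are ideal with respect to the same reference
the validator uses.

Bundles serialize to a directory of JSON files, validated structurally on
load. Archive statistics are rebuilt from per-entry metric records (the
annual-recalculation workflow) with `build_archive_stats`.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GeometryDictionary",
    "RamachandranReference",
    "RotamerLibrary",
    "Rotamer",
    "FragmentStats",
    "ArchiveStats",
    "ShiftRefStats",
    "ReferenceBundle",
    "BundleError",
    "default_bundle",
    "load_reference_bundle",
    "save_reference_bundle",
    "build_archive_stats",
    "fragment_bond_key",
    "fragment_angle_key",
    "RAMA_CLASSES",
    "METRIC_IDS",
    "DEFAULT_BAND_EDGES",
]

RAMA_CLASSES = ("general", "GLY", "PRO", "pre-PRO")
METRIC_IDS = ("Rfree", "clashscore", "rama_outlier_pct", "rotamer_outlier_pct", "rsrz_outlier_pct")
DEFAULT_BAND_EDGES = (0.0, 1.0, 1.4, 1.8, 2.2, 2.6, 3.0, float("inf"))


class BundleError(ValueError):
    """A reference bundle failed structural validation."""


# ---------------------------------------------------------------------------
# covalent geometry

@dataclass
class GeometryDictionary:
    """Target values and sigmas for covalent bonds and angles.

    Keys are (residue name, hyphen-joined atom names); peptide-link entries
    live under the pseudo-residue name 'PEPTIDE-LINK' and span the C/O of
    residue i and the N/CA of residue i+1.
    """

    entries: dict[tuple[str, str], tuple[float, float]]

    LINK = "PEPTIDE-LINK"

    def get(self, resname: str, key: str) -> Optional[tuple[float, float]]:
        return self.entries.get((resname, key))

    def residue_entries(self, resname: str) -> dict[str, tuple[float, float]]:
        return {k: v for (rn, k), v in self.entries.items() if rn == resname}

    def link_entries(self) -> dict[str, tuple[float, float]]:
        return self.residue_entries(self.LINK)

    def validate(self) -> None:
        from .model import STANDARD_AA
        for (rn, key), (target, sigma) in self.entries.items():
            if sigma <= 0:
                raise BundleError(f"geometry entry ({rn},{key}): sigma must be > 0")
        backbone = ("N-CA", "CA-C", "C-O", "N-CA-C", "CA-C-O")
        for aa in STANDARD_AA:
            for key in backbone:
                if (aa, key) not in self.entries:
                    raise BundleError(f"geometry dictionary missing backbone entry ({aa},{key})")


# ---------------------------------------------------------------------------
# Ramachandran reference

@dataclass
class RamachandranReference:
    """Reference (phi, psi) frequency grids per residue class.

    Each grid covers (-180, 180]^2 with square bins; frequencies sum to 1.
    Favored/outlier classification uses highest-density-region contours:
    a bin is favored when the cumulative mass of all bins at least as dense
    is <= favored_level, an outlier when that mass exceeds outlier_level
    (the "<0.5% of the reference" convention corresponds to
    outlier_level = 0.995)."""

    grids: dict[str, np.ndarray]
    bin_width: float
    favored_level: float = 0.95
    outlier_level: float = 0.995
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cls, g in self.grids.items():
            self.grids[cls] = np.asarray(g, dtype=float)

    def validate(self) -> None:
        n = int(round(360.0 / self.bin_width))
        for cls in RAMA_CLASSES:
            if cls not in self.grids:
                raise BundleError(f"ramachandran reference missing class {cls}")
            g = self.grids[cls]
            if g.shape != (n, n):
                raise BundleError(f"ramachandran grid for {cls} has shape {g.shape}, expected {(n, n)}")
            if not np.isclose(g.sum(), 1.0, atol=1e-6):
                raise BundleError(f"ramachandran grid for {cls} does not sum to 1")
            if (g < 0).any():
                raise BundleError(f"ramachandran grid for {cls} has negative frequency")

    def bin_index(self, phi: float, psi: float) -> tuple[int, int]:
        n = self.grids[RAMA_CLASSES[0]].shape[0]
        i = int(np.floor((phi + 180.0) / self.bin_width)) % n
        j = int(np.floor((psi + 180.0) / self.bin_width)) % n
        return i, j

    def hdr_mass(self, cls: str, phi: float, psi: float) -> float:
        """Cumulative mass of all bins at least as dense as the query's bin."""
        cum = self._cum_grid(cls)
        i, j = self.bin_index(phi, psi)
        return float(cum[i, j])

    def _cum_grid(self, cls: str) -> np.ndarray:
        if cls not in self._cum:
            g = self.grids[cls]
            flat = g.ravel()
            order = np.argsort(-flat, kind="stable")
            csum = np.cumsum(flat[order])
            cum = np.empty_like(flat)
            cum[order] = csum
            # ties: every bin with the same density gets the mass including
            # all equally-dense bins, making classification order-independent
            uniq, inv = np.unique(-flat, return_inverse=True)
            maxcum = np.full(uniq.shape, -np.inf)
            np.maximum.at(maxcum, inv, cum)
            cum = maxcum[inv]
            self._cum[cls] = cum.reshape(g.shape)
        return self._cum[cls]


# ---------------------------------------------------------------------------
# rotamer library

@dataclass
class Rotamer:
    name: str
    chi_means: tuple[float, ...]
    chi_sigmas: tuple[float, ...]
    frequency: float


@dataclass
class RotamerLibrary:
    residues: dict[str, list[Rotamer]]

    def get(self, resname: str) -> Optional[list[Rotamer]]:
        return self.residues.get(resname)

    def validate(self) -> None:
        for rn, rots in self.residues.items():
            total = 0.0
            for r in rots:
                if len(r.chi_means) != len(r.chi_sigmas):
                    raise BundleError(f"rotamer {rn}/{r.name}: means/sigmas length mismatch")
                if any(s <= 0 for s in r.chi_sigmas):
                    raise BundleError(f"rotamer {rn}/{r.name}: sigma must be > 0")
                total += r.frequency
            if total > 1.0 + 1e-9:
                raise BundleError(f"rotamer frequencies for {rn} sum to {total} > 1")


# ---------------------------------------------------------------------------
# fragment statistics (ligand geometry)

def _atom_descriptor(element: str, connectivity: int) -> str:
    return f"{element.upper()}{connectivity}"


def fragment_bond_key(desc_a: str, desc_b: str) -> str:
    """Canonical key for a bond fragment: sorted pair of atom descriptors."""
    lo, hi = sorted((desc_a, desc_b))
    return f"{lo}-{hi}"


def fragment_angle_key(desc_left: str, desc_center: str, desc_right: str) -> str:
    """Canonical key for an angle fragment: center atom with sorted outer atoms."""
    lo, hi = sorted((desc_left, desc_right))
    return f"{lo}-{desc_center}-{hi}"


@dataclass
class FragmentStats:
    """Distributions of bond lengths / angles in comparable small-molecule
    fragments, keyed by canonicalized (element, connectivity) descriptors."""

    entries: dict[str, tuple[float, float, int]]  # key -> (mean, sd, n_obs)

    def get(self, key: str) -> Optional[tuple[float, float, int]]:
        return self.entries.get(key)

    def validate(self) -> None:
        for key, (mean, sd, n) in self.entries.items():
            if n >= 2 and sd <= 0:
                raise BundleError(f"fragment entry {key}: sd must be > 0 when n_observations >= 2")


# ---------------------------------------------------------------------------
# archive statistics

@dataclass
class MetricRecord:
    value: float
    resolution: Optional[float]
    method: str


@dataclass
class ArchiveStats:
    """Archive-wide per-entry metric distributions and RSR normalization bands."""

    metrics: dict[str, list[MetricRecord]]
    rsr_norm: dict[tuple[str, int], tuple[float, float]]  # (residue type, band index) -> (mean, sd)
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES
    snapshot_date: str = ""
    directions: dict[str, str] = field(default_factory=lambda: {m: "lower" for m in METRIC_IDS})

    def band_index(self, resolution: float) -> int:
        edges = self.band_edges
        for i in range(len(edges) - 1):
            if edges[i] <= resolution < edges[i + 1]:
                return i
        return len(edges) - 2

    def rsr_band(self, res_type: str, resolution: float) -> Optional[tuple[float, float]]:
        return self.rsr_norm.get((res_type, self.band_index(resolution)))

    def validate(self) -> None:
        for mid, recs in self.metrics.items():
            if not recs:
                raise BundleError(f"archive metric {mid} has no records")
        for (rt, band), (mean, sd) in self.rsr_norm.items():
            if sd <= 0:
                raise BundleError(f"rsr_norm band ({rt},{band}): sd must be > 0")


def build_archive_stats(
    entry_metrics: list[dict],
    snapshot_date: str | None = None,
    rsr_observations: Optional[list[tuple[str, float, float]]] = None,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    min_band_n: int = 2,
) -> ArchiveStats:
    """Aggregate per-entry metric records into archive statistics.

    `entry_metrics` holds one dict per entry with optional keys from
    METRIC_IDS plus 'resolution' and 'method'. `rsr_observations` are
    per-residue (residue type, entry resolution, RSR) submissions used to fit
    the normalization bands. Output is independent of input order.
    """
    if not entry_metrics:
        raise ValueError("build_archive_stats requires at least one entry")
    metrics: dict[str, list[MetricRecord]] = {}
    for mid in METRIC_IDS:
        recs = [
            MetricRecord(float(e[mid]), e.get("resolution"), str(e.get("method", "xray")))
            for e in entry_metrics
            if e.get(mid) is not None
        ]
        if recs:
            recs.sort(key=lambda r: (r.value, r.resolution if r.resolution is not None else -1.0, r.method))
            metrics[mid] = recs

    rsr_norm: dict[tuple[str, int], tuple[float, float]] = {}
    if rsr_observations:
        by_band: dict[tuple[str, int], list[float]] = {}
        stats = ArchiveStats(metrics={}, rsr_norm={}, band_edges=band_edges)
        for res_type, resolution, rsr in rsr_observations:
            by_band.setdefault((res_type, stats.band_index(resolution)), []).append(float(rsr))
        for key, vals in sorted(by_band.items()):
            if len(vals) >= min_band_n:
                arr = np.sort(np.asarray(vals))
                sd = float(arr.std(ddof=1))
                if sd > 0:
                    rsr_norm[key] = (float(arr.mean()), sd)

    if snapshot_date is None:
        snapshot_date = _dt.date.today().isoformat()
    out = ArchiveStats(metrics=metrics, rsr_norm=rsr_norm,
                       band_edges=tuple(band_edges), snapshot_date=snapshot_date)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# chemical-shift statistics

@dataclass
class ShiftRefStats:
    """Mean/sd of chemical shifts keyed by (residue, atom, nucleus); residue
    '*' is a wildcard fallback."""

    entries: dict[tuple[str, str, str], tuple[float, float]]

    def get(self, resname: str, atom: str, nucleus: str) -> Optional[tuple[float, float]]:
        hit = self.entries.get((resname, atom, nucleus))
        if hit is None:
            hit = self.entries.get(("*", atom, nucleus))
        return hit

    def validate(self) -> None:
        for key, (mean, sd) in self.entries.items():
            if sd <= 0:
                raise BundleError(f"shift stats entry {key}: sd must be > 0")


# ---------------------------------------------------------------------------
# the aggregate bundle

@dataclass
class ReferenceBundle:
    geometry: GeometryDictionary
    ramachandran: RamachandranReference
    rotamers: RotamerLibrary
    fragments: FragmentStats
    shifts: ShiftRefStats
    archive: Optional[ArchiveStats] = None
    vdw_radii: dict[str, float] = field(default_factory=dict)
    covalent_radii: dict[str, float] = field(default_factory=dict)
    chirality: dict[str, dict[str, float]] = field(default_factory=dict)
    expected_atoms: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    @property
    def density_fit_available(self) -> bool:
        return self.archive is not None and bool(self.archive.rsr_norm)

    def validate(self) -> None:
        self.geometry.validate()
        self.ramachandran.validate()
        self.rotamers.validate()
        self.fragments.validate()
        self.shifts.validate()
        if self.archive is not None:
            self.archive.validate()


# ---------------------------------------------------------------------------
# default bundle construction

_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
              "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
              "FE": 1.80, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75, "CA": 2.31}
_COV_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
              "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
              "FE": 1.32, "ZN": 1.22, "MG": 1.41}

# Backbone covalent targets (Engh–Huber-style restraint values).
_BACKBONE_BONDS = {"N-CA": (1.459, 0.020), "CA-C": (1.525, 0.026), "C-O": (1.229, 0.019)}
_BACKBONE_ANGLES = {"N-CA-C": (111.0, 2.8), "CA-C-O": (120.1, 2.1)}
_CB_BOND = ("CA-CB", (1.530, 0.020))
_CB_ANGLES = {"N-CA-CB": (110.6, 1.8), "CB-CA-C": (110.4, 2.0)}
_SIDE_CHAIN = {
    "SER": {"CB-OG": (1.417, 0.020), "CA-CB-OG": (111.1, 2.0)},
    "CYS": {"CB-SG": (1.808, 0.033), "CA-CB-SG": (114.4, 2.3)},
    "THR": {"CB-OG1": (1.428, 0.020), "CA-CB-OG1": (109.6, 2.0)},
}
_LINK_ENTRIES = {"C-N": (1.336, 0.023), "CA-C-N": (117.2, 2.2), "C-N-CA": (121.7, 2.5)}


def _default_geometry() -> GeometryDictionary:
    from .model import STANDARD_AA
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for aa in STANDARD_AA:
        for k, v in _BACKBONE_BONDS.items():
            entries[(aa, k)] = v
        for k, v in _BACKBONE_ANGLES.items():
            entries[(aa, k)] = v
        if aa != "GLY":
            entries[(aa, _CB_BOND[0])] = _CB_BOND[1]
            for k, v in _CB_ANGLES.items():
                entries[(aa, k)] = v
        for k, v in _SIDE_CHAIN.get(aa, {}).items():
            entries[(aa, k)] = v
    for k, v in _LINK_ENTRIES.items():
        entries[(GeometryDictionary.LINK, k)] = v
    return GeometryDictionary(entries)


def _wrapped_gaussian(grid_centers: np.ndarray, mu: float, sd: float) -> np.ndarray:
    out = np.zeros_like(grid_centers)
    for period in (-360.0, 0.0, 360.0):
        out += np.exp(-0.5 * ((grid_centers - mu + period) / sd) ** 2)
    return out


def _mixture_grid(components: list[tuple[float, float, float, float, float]],
                  bin_width: float) -> np.ndarray:
    """Grid from a mixture of periodic 2D Gaussians.

    Components are (weight, mu_phi, mu_psi, sd_phi, sd_psi)."""
    n = int(round(360.0 / bin_width))
    centers = -180.0 + bin_width * (np.arange(n) + 0.5)
    g = np.zeros((n, n))
    for w, mphi, mpsi, sphi, spsi in components:
        g += w * np.outer(_wrapped_gaussian(centers, mphi, sphi),
                          _wrapped_gaussian(centers, mpsi, spsi))
    g += 1e-12  # floor avoids exact-zero ties across the whole far field
    return g / g.sum()


def _default_ramachandran(bin_width: float = 4.0) -> RamachandranReference:
    helix = (-63.0, -43.0, 12.0, 12.0)
    sheet = (-120.0, 135.0, 25.0, 25.0)
    lhelix = (60.0, 45.0, 10.0, 10.0)
    comp = {
        "general": [(0.55, *helix), (0.40, *sheet), (0.05, *lhelix)],
        "GLY": [(0.33, *helix), (0.27, *sheet), (0.25, *lhelix),
                (0.15, 85.0, -170.0, 20.0, 20.0)],
        "PRO": [(0.60, -63.0, -35.0, 8.0, 10.0), (0.40, -63.0, 150.0, 8.0, 15.0)],
        "pre-PRO": [(0.45, *helix), (0.45, -125.0, 125.0, 25.0, 25.0), (0.10, *lhelix)],
    }
    grids = {cls: _mixture_grid(c, bin_width) for cls, c in comp.items()}
    return RamachandranReference(grids=grids, bin_width=bin_width)


def _default_rotamers() -> RotamerLibrary:
    chi1 = [("m", -65.0), ("t", 180.0), ("p", 65.0)]
    sd = 12.0
    residues: dict[str, list[Rotamer]] = {}
    for rn in ("SER", "CYS", "THR", "VAL"):
        freqs = {"SER": (0.48, 0.29, 0.23), "CYS": (0.55, 0.30, 0.15),
                 "THR": (0.45, 0.10, 0.45), "VAL": (0.25, 0.70, 0.05)}[rn]
        residues[rn] = [Rotamer(nm, (mu,), (sd,), f)
                        for (nm, mu), f in zip(chi1, freqs)]
    for rn in ("LEU", "ILE", "PHE", "TYR", "TRP", "HIS", "ASP", "ASN"):
        residues[rn] = [
            Rotamer("mt", (-65.0, 175.0), (sd, 15.0), 0.55),
            Rotamer("tp", (180.0, 65.0), (sd, 15.0), 0.25),
            Rotamer("tt", (180.0, 175.0), (sd, 15.0), 0.15),
        ]
    for rn in ("GLU", "GLN", "MET"):
        residues[rn] = [
            Rotamer("mtm", (-65.0, 180.0, -65.0), (sd, 15.0, 20.0), 0.40),
            Rotamer("ttt", (180.0, 180.0, 180.0), (sd, 15.0, 20.0), 0.30),
        ]
    for rn in ("LYS", "ARG"):
        residues[rn] = [
            Rotamer("mttt", (-65.0, 180.0, 180.0, 180.0), (sd, 15.0, 15.0, 20.0), 0.40),
            Rotamer("tttt", (180.0, 180.0, 180.0, 180.0), (sd, 15.0, 15.0, 20.0), 0.35),
        ]
    residues["PRO"] = [Rotamer("down", (25.0, -35.0), (8.0, 8.0), 0.5),
                       Rotamer("up", (-25.0, 35.0), (8.0, 8.0), 0.5)]
    return RotamerLibrary(residues)


def _default_fragments() -> FragmentStats:
    # Means/sds in the style of small-molecule survey distributions; keys are
    # (element, connectivity) descriptor pairs/triples.
    entries = {
        fragment_bond_key("C1", "C3"): (1.52, 0.015, 400),
        fragment_angle_key("C1", "C3", "C1"): (110.5, 2.0, 300),
        fragment_angle_key("C1", "C3", "O1"): (109.5, 2.1, 250),
        fragment_bond_key("C2", "C3"): (1.50, 0.015, 500),
        fragment_bond_key("C3", "C3"): (1.53, 0.016, 800),
        fragment_bond_key("C2", "C2"): (1.46, 0.020, 300),
        fragment_bond_key("C3", "O1"): (1.42, 0.015, 400),
        fragment_bond_key("C2", "O1"): (1.22, 0.012, 600),
        fragment_bond_key("C3", "O2"): (1.43, 0.015, 350),
        fragment_bond_key("C2", "O2"): (1.34, 0.014, 250),
        fragment_bond_key("C3", "N3"): (1.47, 0.015, 450),
        fragment_bond_key("C2", "N3"): (1.35, 0.014, 300),
        fragment_angle_key("C3", "C3", "C3"): (111.0, 2.0, 500),
        fragment_angle_key("C3", "C3", "O1"): (110.0, 2.2, 300),
        fragment_angle_key("C3", "C3", "N3"): (111.5, 2.1, 280),
        fragment_angle_key("C3", "C2", "O1"): (121.0, 1.8, 350),
        fragment_angle_key("O1", "C2", "O2"): (123.0, 1.9, 200),
        fragment_angle_key("C3", "C2", "O2"): (116.0, 1.9, 200),
        fragment_angle_key("C2", "C3", "C3"): (112.0, 2.2, 260),
        fragment_angle_key("C3", "O2", "C3"): (113.0, 2.3, 150),
    }
    return FragmentStats(entries)


def _default_shift_stats() -> ShiftRefStats:
    generic = {
        ("*", "H", "1H"): (8.30, 0.65), ("*", "HA", "1H"): (4.45, 0.45),
        ("*", "HB", "1H"): (2.0, 0.7), ("*", "N", "15N"): (119.0, 4.5),
        ("*", "CA", "13C"): (58.0, 3.2), ("*", "CB", "13C"): (33.0, 5.5),
        ("*", "C", "13C"): (176.0, 2.0),
        ("ALA", "CA", "13C"): (53.1, 2.0), ("ALA", "CB", "13C"): (19.0, 1.8),
        ("GLY", "CA", "13C"): (45.4, 1.3),
        ("SER", "CA", "13C"): (58.7, 2.1), ("SER", "CB", "13C"): (63.8, 1.5),
    }
    return ShiftRefStats(generic)


# Expected sign of the signed volume det[N-CA, C-CA, CB-CA] at an L-amino
# acid alpha carbon (positive for the L configuration).
_CHIRALITY = {
    aa: {"CA": 1.0}
    for aa in ("ALA ARG ASN ASP CYS GLN GLU HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split())
}

_EXPECTED_ATOMS = {
    "backbone": {"*": ["N", "H", "CA", "HA", "C"]},
    "sidechain-aliphatic": {
        "ALA": ["CB", "HB"], "SER": ["CB", "HB", "OG"], "CYS": ["CB", "HB", "SG"],
        "VAL": ["CB", "HB", "CG1", "CG2"], "LEU": ["CB", "HB", "CG", "CD1", "CD2"],
        "ILE": ["CB", "HB", "CG1", "CG2", "CD1"], "THR": ["CB", "HB", "OG1", "CG2"],
        "MET": ["CB", "HB", "CG", "SD", "CE"], "LYS": ["CB", "HB", "CG", "CD", "CE", "NZ"],
        "ARG": ["CB", "HB", "CG", "CD", "NE", "CZ"], "PRO": ["CB", "HB", "CG", "CD"],
        "ASP": ["CB", "HB", "CG"], "ASN": ["CB", "HB", "CG", "ND2"],
        "GLU": ["CB", "HB", "CG", "CD"], "GLN": ["CB", "HB", "CG", "CD", "NE2"],
    },
    "sidechain-aromatic": {
        "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    },
}


def default_bundle(archive: Optional[ArchiveStats] = None) -> ReferenceBundle:
    """The packaged reference bundle, generated from documented families."""
    bundle = ReferenceBundle(
        geometry=_default_geometry(),
        ramachandran=_default_ramachandran(),
        rotamers=_default_rotamers(),
        fragments=_default_fragments(),
        shifts=_default_shift_stats(),
        archive=archive,
        vdw_radii=dict(_VDW_RADII),
        covalent_radii=dict(_COV_RADII),
        chirality={k: dict(v) for k, v in _CHIRALITY.items()},
        expected_atoms={k: {r: list(a) for r, a in v.items()} for k, v in _EXPECTED_ATOMS.items()},
        versions={"strucval-reference": "builtin-1.0"},
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# JSON serialization

def _require(obj: dict, key: str, typ, fname: str):
    if key not in obj:
        raise BundleError(f"{fname}: missing field '{key}'")
    val = obj[key]
    if typ is float and isinstance(val, int):
        val = float(val)
    if not isinstance(val, typ):
        raise BundleError(f"{fname}: field '{key}' has wrong type {type(val).__name__}")
    return val


def save_reference_bundle(bundle: ReferenceBundle, path: str) -> None:
    os.makedirs(path, exist_ok=True)

    def dump(name: str, obj) -> None:
        with open(os.path.join(path, name), "w") as fh:
            json.dump(obj, fh, sort_keys=True)

    dump("geometry.json", {
        "entries": [{"residue": rn, "key": k, "target": t, "sigma": s}
                    for (rn, k), (t, s) in sorted(bundle.geometry.entries.items())]})
    dump("ramachandran.json", {
        "bin_width": bundle.ramachandran.bin_width,
        "favored_level": bundle.ramachandran.favored_level,
        "outlier_level": bundle.ramachandran.outlier_level,
        "grids": {cls: g.tolist() for cls, g in bundle.ramachandran.grids.items()}})
    dump("rotamers.json", {
        "residues": {rn: [{"name": r.name, "chi_means": list(r.chi_means),
                           "chi_sigmas": list(r.chi_sigmas), "frequency": r.frequency}
                          for r in rots]
                     for rn, rots in bundle.rotamers.residues.items()}})
    dump("fragments.json", {
        "entries": [{"key": k, "mean": m, "sd": s, "n_observations": n}
                    for k, (m, s, n) in sorted(bundle.fragments.entries.items())]})
    dump("shifts.json", {
        "entries": [{"residue": r, "atom": a, "nucleus": nu, "mean": m, "sd": s}
                    for (r, a, nu), (m, s) in sorted(bundle.shifts.entries.items())]})
    dump("tables.json", {
        "vdw_radii": bundle.vdw_radii, "covalent_radii": bundle.covalent_radii,
        "chirality": bundle.chirality, "expected_atoms": bundle.expected_atoms,
        "versions": bundle.versions})
    if bundle.archive is not None:
        save_archive_stats(bundle.archive, os.path.join(path, "archive.json"))


def save_archive_stats(stats: ArchiveStats, path: str) -> None:
    obj = {
        "snapshot_date": stats.snapshot_date,
        "band_edges": [e if np.isfinite(e) else None for e in stats.band_edges],
        "directions": stats.directions,
        "metrics": {mid: [{"value": r.value, "resolution": r.resolution, "method": r.method}
                          for r in recs]
                    for mid, recs in stats.metrics.items()},
        "rsr_norm": [{"residue": rt, "band": b, "mean": m, "sd": s}
                     for (rt, b), (m, s) in sorted(stats.rsr_norm.items())],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def load_archive_stats(path: str) -> ArchiveStats:
    fname = os.path.basename(path)
    with open(path) as fh:
        obj = json.load(fh)
    edges = tuple(float("inf") if e is None else float(e)
                  for e in _require(obj, "band_edges", list, fname))
    metrics = {}
    for mid, recs in _require(obj, "metrics", dict, fname).items():
        metrics[mid] = [MetricRecord(_require(r, "value", (int, float), fname),
                                     r.get("resolution"), r.get("method", "xray"))
                        for r in recs]
    rsr_norm = {}
    for rec in _require(obj, "rsr_norm", list, fname):
        sd = _require(rec, "sd", (int, float), fname)
        if sd <= 0:
            raise BundleError(f"{fname}: rsr_norm sd must be > 0 "
                              f"(residue {rec.get('residue')}, band {rec.get('band')})")
        rsr_norm[(rec["residue"], int(rec["band"]))] = (float(rec["mean"]), float(sd))
    stats = ArchiveStats(metrics=metrics, rsr_norm=rsr_norm, band_edges=edges,
                         snapshot_date=obj.get("snapshot_date", ""),
                         directions=obj.get("directions", {m: "lower" for m in METRIC_IDS}))
    stats.validate()
    return stats


def load_reference_bundle(path: str) -> ReferenceBundle:
    """Load a bundle directory, structurally validating every file.

    A missing archive.json (or one without rsr_norm bands) is allowed; the
    bundle then reports density-fit normalization as unavailable."""

    def read(name: str) -> dict:
        fpath = os.path.join(path, name)
        if not os.path.exists(fpath):
            raise BundleError(f"bundle missing required file {name}")
        with open(fpath) as fh:
            try:
                return json.load(fh)
            except json.JSONDecodeError as exc:
                raise BundleError(f"{name}: invalid JSON: {exc}") from exc

    g = read("geometry.json")
    geometry = GeometryDictionary({})
    for ent in _require(g, "entries", list, "geometry.json"):
        sigma = _require(ent, "sigma", (int, float), "geometry.json")
        if sigma <= 0:
            raise BundleError(f"geometry.json: sigma must be > 0 for entry "
                              f"({ent.get('residue')},{ent.get('key')})")
        geometry.entries[(ent["residue"], ent["key"])] = (float(ent["target"]), float(sigma))

    r = read("ramachandran.json")
    rama = RamachandranReference(
        grids={cls: np.asarray(grid, dtype=float)
               for cls, grid in _require(r, "grids", dict, "ramachandran.json").items()},
        bin_width=float(_require(r, "bin_width", (int, float), "ramachandran.json")),
        favored_level=float(r.get("favored_level", 0.95)),
        outlier_level=float(r.get("outlier_level", 0.995)),
    )

    ro = read("rotamers.json")
    rotamers = RotamerLibrary({
        rn: [Rotamer(e["name"], tuple(e["chi_means"]), tuple(e["chi_sigmas"]), float(e["frequency"]))
             for e in rots]
        for rn, rots in _require(ro, "residues", dict, "rotamers.json").items()})

    f = read("fragments.json")
    fragments = FragmentStats({
        ent["key"]: (float(ent["mean"]), float(ent["sd"]), int(ent["n_observations"]))
        for ent in _require(f, "entries", list, "fragments.json")})

    s = read("shifts.json")
    shifts = ShiftRefStats({
        (e["residue"], e["atom"], e["nucleus"]): (float(e["mean"]), float(e["sd"]))
        for e in _require(s, "entries", list, "shifts.json")})

    t = read("tables.json")
    archive = None
    apath = os.path.join(path, "archive.json")
    if os.path.exists(apath):
        archive = load_archive_stats(apath)

    bundle = ReferenceBundle(
        geometry=geometry, ramachandran=rama, rotamers=rotamers,
        fragments=fragments, shifts=shifts, archive=archive,
        vdw_radii=_require(t, "vdw_radii", dict, "tables.json"),
        covalent_radii=_require(t, "covalent_radii", dict, "tables.json"),
        chirality=t.get("chirality", {}),
        expected_atoms=t.get("expected_atoms", {}),
        versions=t.get("versions", {}),
    )
    bundle.validate()
    return bundle
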