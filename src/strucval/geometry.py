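"""Knowledge-based model validation.

Covers the coordinate-only checks: covalent bond/angle deviations against a
restraint dictionary, Ramachandran and rotamer classification, non-bonded
clashes (including crystallographic symmetry contacts), cis/twisted peptide
detection, chirality checks, and fragment-statistics comparison for ligands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    Atom,
    Residue,
    ResidueKind,
    StructureModel,
    TorsionSet,
    bond_angle,
    compute_torsions,
    symmetry_images,
)
from .refdata import (
    GeometryDictionary,
    FragmentStats,
    RamachandranReference,
    ReferenceBundle,
    Rotamer,
    fragment_angle_key,
    fragment_bond_key,
)

__all__ = [
    "GeomDeviation",
    "Clash",
    "ResidueGeometrySummary",
    "covalent_deviations",
    "rmsz",
    "classify_ramachandran",
    "rama_class_of",
    "classify_rotamer",
    "find_clashes",
    "clashscore",
    "detect_cis_peptides",
    "classify_omega",
    "check_chirality",
    "ligand_fragment_deviations",
    "residue_connectivity",
    "validate_geometry",
    "COVALENT_OUTLIER_Z",
    "LIGAND_OUTLIER_Z",
    "ROTAMER_Z",
    "CLASH_OVERLAP_THRESHOLD",
]

# Default thresholds (all configurable at call sites).
COVALENT_OUTLIER_Z = 4.0
LIGAND_OUTLIER_Z = 2.0
ROTAMER_Z = 3.0
CLASH_OVERLAP_THRESHOLD = 0.4
CIS_CUT = 30.0
TWISTED_CUT = 150.0

CRITERIA = ("bond-length", "bond-angle", "ramachandran", "rotamer-or-torsion",
            "clash", "chirality")


@dataclass
class GeomDeviation:
    key: str
    kind: str  # 'bond' or 'angle'
    observed: float
    target: float
    sigma: float
    residue: Optional[tuple[str, int, str]] = None

    @property
    def z(self) -> float:
        return (self.observed - self.target) / self.sigma

    def is_outlier(self, threshold: float = COVALENT_OUTLIER_Z) -> bool:
        return abs(self.z) > threshold


@dataclass
class Clash:
    atom_a: tuple[tuple[str, int, str], str]   # (residue key, atom name)
    atom_b: tuple[tuple[str, int, str], str]
    distance: float
    overlap: float
    symmetry: bool = False


@dataclass
class ResidueGeometrySummary:
    residue: tuple[str, int, str]
    name: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CRITERIA})
    rama_class: str = "n/a"       # favored | allowed | outlier | n/a
    rotamer_class: str = "n/a"    # rotameric | outlier | n/a
    rotamer_name: Optional[str] = None
    cis_peptide: bool = False
    torsions: Optional[TorsionSet] = None

    @property
    def outlier_types(self) -> set[str]:
        return {c for c, n in self.counts.items() if n > 0}


# ---------------------------------------------------------------------------
# covalent geometry

def _atoms_for_key(key: str, residue: Residue, next_residue: Optional[Residue],
                   link: bool) -> Optional[list[np.ndarray]]:
    names = key.split("-")
    coords = []
    for idx, nm in enumerate(names):
        # in link entries the trailing N/CA belong to the following residue
        if link and nm in ("N", "CA") and idx > 0:
            src = next_residue
        else:
            src = residue
        if src is None:
            return None
        a = src.get_atom(nm)
        if a is None:
            return None
        coords.append(a.pos)
    return coords


def covalent_deviations(
    residue: Residue,
    next_residue: Optional[Residue],
    geometry: GeometryDictionary,
) -> list[GeomDeviation]:
    """Deviations of this residue's bonds/angles from dictionary targets.

    Includes the peptide-link entries to `next_residue` when it is present
    and covalently linked. Entries whose atoms are missing are skipped."""
    out: list[GeomDeviation] = []
    groups: list[tuple[str, dict, bool]] = [(residue.name, geometry.residue_entries(residue.name), False)]
    if next_residue is not None and _is_linked(residue, next_residue):
        groups.append((GeometryDictionary.LINK, geometry.link_entries(), True))
    for _, entries, link in groups:
        for key, (target, sigma) in entries.items():
            coords = _atoms_for_key(key, residue, next_residue, link)
            if coords is None:
                continue
            if len(coords) == 2:
                obs = float(np.linalg.norm(coords[0] - coords[1]))
                kind = "bond"
            else:
                obs = bond_angle(*coords)
                kind = "angle"
            out.append(GeomDeviation(key=key, kind=kind, observed=obs,
                                     target=target, sigma=sigma, residue=residue.key))
    return out


def _is_linked(r1: Residue, r2: Residue, max_cn: float = 2.0) -> bool:
    c, n = r1.get_atom("C"), r2.get_atom("N")
    return c is not None and n is not None and float(np.linalg.norm(c.pos - n.pos)) < max_cn


def rmsz(z_values: Iterable[float]) -> Optional[float]:
    """Root-mean-square of Z scores; None for an empty input."""
    zs = np.asarray(list(z_values), dtype=float)
    if zs.size == 0:
        return None
    return float(np.sqrt(np.mean(zs ** 2)))


# ---------------------------------------------------------------------------
# torsion classification

def rama_class_of(residue: Residue, next_residue: Optional[Residue]) -> str:
    if residue.name == "GLY":
        return "GLY"
    if residue.name == "PRO":
        return "PRO"
    if next_residue is not None and next_residue.name == "PRO":
        return "pre-PRO"
    return "general"


def classify_ramachandran(phi: float, psi: float, res_class: str,
                          ref: RamachandranReference) -> str:
    """favored / allowed / outlier by highest-density-region contour."""
    mass = ref.hdr_mass(res_class, phi, psi)
    if mass <= ref.favored_level:
        return "favored"
    if mass <= ref.outlier_level:
        return "allowed"
    return "outlier"


def circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_rotamer(chis: Sequence[Optional[float]], rotamers: Sequence[Rotamer],
                     rotamer_z: float = ROTAMER_Z) -> tuple[Optional[str], bool]:
    """Nearest rotamer (by max per-chi circular Z) and outlier flag.

    Returns (None, False) when the residue has no defined chis to classify.
    Ties in the nearest-rotamer score break by library order."""
    defined = [c for c in chis if c is not None]
    if not rotamers or not defined:
        return None, False
    best_name: Optional[str] = None
    best_score = math.inf
    for rot in rotamers:
        n = min(len(chis), len(rot.chi_means))
        scores = [circular_distance(chis[i], rot.chi_means[i]) / rot.chi_sigmas[i]
                  for i in range(n) if chis[i] is not None]
        if not scores:
            continue
        score = max(scores)
        if score < best_score - 1e-12:
            best_score = score
            best_name = rot.name
    return best_name, best_score > rotamer_z


def classify_omega(omega: float) -> str:
    a = abs(omega)
    if a < CIS_CUT:
        return "cis"
    if a <= TWISTED_CUT:
        return "twisted"
    return "trans"


def detect_cis_peptides(omegas: Sequence[Optional[float]]) -> list[Optional[str]]:
    """Classify each peptide link's omega as trans/cis/twisted (None skipped)."""
    return [None if w is None else classify_omega(w) for w in omegas]


# ---------------------------------------------------------------------------
# chirality

def check_chirality(residue: Residue, expected: dict[str, dict[str, float]]) -> list[str]:
    """Stereocenter sign-of-volume checks; returns violated center names.

    The supported centers are alpha carbons: the signed volume
    det[N-CA, C-CA, CB-CA] must match the expected sign (positive = L).
    Centers with missing substituents are skipped."""
    table = expected.get(residue.name, {})
    violations = []
    for center, sign in table.items():
        if center != "CA":
            continue
        atoms = [residue.get_atom(nm) for nm in ("CA", "N", "C", "CB")]
        if any(a is None for a in atoms):
            continue
        ca, n, c, cb = (a.pos for a in atoms)
        vol = float(np.linalg.det(np.stack([n - ca, c - ca, cb - ca])))
        if vol * sign < 0:
            violations.append(center)
    return violations


# ---------------------------------------------------------------------------
# clashes

def residue_connectivity(residue: Residue, cov_radii: dict[str, float],
                         tol: float = 0.4) -> list[tuple[str, str]]:
    """Intra-residue bonds inferred from covalent radii (distance fallback)."""
    atoms = residue.effective_atoms()
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            cutoff = cov_radii.get(a.element.upper(), 0.77) + cov_radii.get(b.element.upper(), 0.77) + tol
            if float(np.linalg.norm(a.pos - b.pos)) <= cutoff:
                bonds.append((a.name, b.name))
    return bonds


def _bond_graph(structure: StructureModel, cov_radii: dict[str, float],
                include_hydrogens: bool) -> tuple[list[tuple[Residue, Atom]], dict[int, set[int]]]:
    """Global bond adjacency over effective atoms (indices into the atom list)."""
    pairs = structure.all_atoms(include_hydrogens=include_hydrogens)
    index: dict[tuple[tuple[str, int, str], str], int] = {
        (res.key, atom.name): i for i, (res, atom) in enumerate(pairs)
    }
    adj: dict[int, set[int]] = {i: set() for i in range(len(pairs))}

    def connect(i: int, j: int) -> None:
        adj[i].add(j)
        adj[j].add(i)

    for residues in structure.chains.values():
        for k, res in enumerate(residues):
            for a_name, b_name in residue_connectivity(res, cov_radii):
                ia, ib = index.get((res.key, a_name)), index.get((res.key, b_name))
                if ia is not None and ib is not None:
                    connect(ia, ib)
            if k + 1 < len(residues) and _is_linked(res, residues[k + 1]):
                ia = index.get((res.key, "C"))
                ib = index.get((residues[k + 1].key, "N"))
                if ia is not None and ib is not None:
                    connect(ia, ib)
    return pairs, adj


def _excluded_pairs(adj: dict[int, set[int]]) -> set[frozenset]:
    """Bonded (1-2), angle (1-3) and torsion (1-4) pairs.

    1-4 pairs are excluded because their separation is fixed by a torsion,
    not by a non-bonded contact: in an ideal trans peptide the carbonyl O to
    next-residue CA distance (~2.8 A) already exceeds the 0.4 A overlap cut."""
    excl: set[frozenset] = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excl.add(frozenset((i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add(frozenset((i, k)))
                    for m in adj[k]:
                        if m != i and m != j:
                            excl.add(frozenset((i, m)))
    return excl


def find_clashes(
    structure: StructureModel,
    vdw_radii: dict[str, float],
    cov_radii: dict[str, float],
    overlap_threshold: float = CLASH_OVERLAP_THRESHOLD,
    include_hydrogens: bool = False,
    include_symmetry: bool = True,
    default_radius: float = 1.70,
) -> list[Clash]:
    """All non-bonded atom pairs with vdW overlap >= threshold.

    Excludes bonded and 1-3 pairs and disulfide-bridged sulfur pairs. With a
    real unit cell, contacts to symmetry/lattice images are included, each
    counted once (canonical pair key). Uses a k-d tree; results are identical
    to an all-pairs scan."""
    pairs, adj = _bond_graph(structure, cov_radii, include_hydrogens)
    if not pairs:
        return []
    excl = _excluded_pairs(adj)

    def radius_of(atom: Atom) -> float:
        return vdw_radii.get(atom.element.upper(), default_radius)

    coords = np.array([a.pos for _, a in pairs])
    radii = np.array([radius_of(a) for _, a in pairs])
    max_r = float(radii.max())
    cutoff = 2.0 * max_r - overlap_threshold

    tree = cKDTree(coords)
    clashes: list[Clash] = []
    seen: set = set()
    for i, j in tree.query_pairs(cutoff):
        if frozenset((i, j)) in excl:
            continue
        res_i, atom_i = pairs[i]
        res_j, atom_j = pairs[j]
        # disulfide bridge: two cysteine sulfurs at bonding distance
        if atom_i.element.upper() == "S" and atom_j.element.upper() == "S":
            if float(np.linalg.norm(atom_i.pos - atom_j.pos)) < 2.5:
                continue
        d = float(np.linalg.norm(atom_i.pos - atom_j.pos))
        overlap = radii[i] + radii[j] - d
        if overlap >= overlap_threshold:
            a_key, b_key = sorted([(res_i.key, atom_i.name), (res_j.key, atom_j.name)])
            clashes.append(Clash(a_key, b_key, d, overlap))

    if include_symmetry and structure.cell is not None and not structure.cell_is_placeholder:
        sym_radius = cutoff
        for res, atom, image, op, shift in symmetry_images(structure, sym_radius,
                                                           include_hydrogens=include_hydrogens):
            r_img = radius_of(image)
            d_arr, idx_arr = tree.query(image.pos, k=len(pairs),
                                        distance_upper_bound=sym_radius)
            src_key = (res.key, atom.name)
            for d, idx in zip(np.atleast_1d(d_arr), np.atleast_1d(idx_arr)):
                if not np.isfinite(d) or idx >= len(pairs):
                    continue
                res_j, atom_j = pairs[idx]
                overlap = r_img + radii[idx] - float(d)
                if overlap < overlap_threshold:
                    continue
                if d < 1e-6:
                    continue  # atom on a special position mapping to itself
                dst_key = (res_j.key, atom_j.name)
                # clash (a, image of b) duplicates (b, image of a) under the
                # inverse op: canonicalize by the sorted key pair + distance
                canon = (min(src_key, dst_key), max(src_key, dst_key), round(float(d), 6))
                if canon in seen:
                    continue
                seen.add(canon)
                clashes.append(Clash(min(src_key, dst_key), max(src_key, dst_key),
                                     float(d), overlap, symmetry=True))
    return clashes


def clashscore(n_clashes: int, n_atoms: int) -> Optional[float]:
    """Serious clashes per 1,000 atoms; None when the atom count is zero."""
    if n_atoms <= 0:
        return None
    return 1000.0 * n_clashes / n_atoms


# ---------------------------------------------------------------------------
# ligand fragment comparison

@dataclass
class LigandGeometryResult:
    deviations: list[GeomDeviation]
    bond_rmsz: Optional[float]
    angle_rmsz: Optional[float]
    n_matched: int
    n_unmatched: int

    def outliers(self, threshold: float = LIGAND_OUTLIER_Z) -> list[GeomDeviation]:
        return [d for d in self.deviations if abs(d.z) > threshold]


def ligand_fragment_deviations(
    ligand: Residue,
    stats: FragmentStats,
    bonds: Optional[list[tuple[str, str]]] = None,
    cov_radii: Optional[dict[str, float]] = None,
) -> LigandGeometryResult:
    """Compare a ligand's bonds/angles against fragment statistics.

    Connectivity comes from `bonds` (atom-name pairs) or, when omitted, from
    the covalent-radius distance fallback. Fragments without a statistics
    entry are counted as unmatched, not scored."""
    if bonds is None:
        if cov_radii is None:
            raise ValueError("either bonds or cov_radii must be supplied")
        bonds = residue_connectivity(ligand, cov_radii)

    atoms = {a.name: a for a in ligand.effective_atoms(include_hydrogens=False)}
    adj: dict[str, set[str]] = {nm: set() for nm in atoms}
    for a, b in bonds:
        if a in atoms and b in atoms:
            adj[a].add(b)
            adj[b].add(a)
    desc = {nm: f"{atoms[nm].element.upper()}{len(adj[nm])}" for nm in atoms}

    deviations: list[GeomDeviation] = []
    n_matched = n_unmatched = 0

    for a, b in bonds:
        if a not in atoms or b not in atoms:
            continue
        key = fragment_bond_key(desc[a], desc[b])
        entry = stats.get(key)
        if entry is None:
            n_unmatched += 1
            continue
        mean, sd, _ = entry
        obs = float(np.linalg.norm(atoms[a].pos - atoms[b].pos))
        deviations.append(GeomDeviation(key=f"{a}-{b}|{key}", kind="bond",
                                        observed=obs, target=mean, sigma=sd,
                                        residue=ligand.key))
        n_matched += 1

    for center, nbrs in adj.items():
        nbr_list = sorted(nbrs)
        for i in range(len(nbr_list)):
            for j in range(i + 1, len(nbr_list)):
                left, right = nbr_list[i], nbr_list[j]
                key = fragment_angle_key(desc[left], desc[center], desc[right])
                entry = stats.get(key)
                if entry is None:
                    n_unmatched += 1
                    continue
                mean, sd, _ = entry
                obs = bond_angle(atoms[left].pos, atoms[center].pos, atoms[right].pos)
                deviations.append(GeomDeviation(key=f"{left}-{center}-{right}|{key}",
                                                kind="angle", observed=obs,
                                                target=mean, sigma=sd,
                                                residue=ligand.key))
                n_matched += 1

    bond_z = [d.z for d in deviations if d.kind == "bond"]
    angle_z = [d.z for d in deviations if d.kind == "angle"]
    return LigandGeometryResult(
        deviations=deviations,
        bond_rmsz=rmsz(bond_z),
        angle_rmsz=rmsz(angle_z),
        n_matched=n_matched,
        n_unmatched=n_unmatched,
    )


# ---------------------------------------------------------------------------
# whole-structure orchestration

@dataclass
class GeometryValidationResult:
    summaries: dict[tuple[str, int, str], ResidueGeometrySummary]
    clashes: list[Clash]

    def __getitem__(self, key):
        return self.summaries[key]

    def values(self):
        return self.summaries.values()


def validate_geometry(
    structure: StructureModel,
    bundle: ReferenceBundle,
    covalent_z: float = COVALENT_OUTLIER_Z,
    rotamer_z: float = ROTAMER_Z,
    overlap_threshold: float = CLASH_OVERLAP_THRESHOLD,
    include_symmetry: bool = True,
) -> GeometryValidationResult:
    """Run every coordinate-only check and summarize per residue."""
    summaries: dict[tuple[str, int, str], ResidueGeometrySummary] = {}
    for res in structure.residues():
        summaries[res.key] = ResidueGeometrySummary(residue=res.key, name=res.name)

    for cid, residues in structure.chains.items():
        torsions = compute_torsions(residues)
        for k, res in enumerate(residues):
            summ = summaries[res.key]
            summ.torsions = torsions[k]
            nxt = residues[k + 1] if k + 1 < len(residues) else None
            if res.kind != ResidueKind.STANDARD_AA:
                continue
            for dev in covalent_deviations(res, nxt, bundle.geometry):
                if dev.is_outlier(covalent_z):
                    crit = "bond-length" if dev.kind == "bond" else "bond-angle"
                    summ.counts[crit] += 1
            ts = torsions[k]
            if ts.phi is not None and ts.psi is not None:
                cls = rama_class_of(res, nxt)
                summ.rama_class = classify_ramachandran(ts.phi, ts.psi, cls,
                                                        bundle.ramachandran)
                if summ.rama_class == "outlier":
                    summ.counts["ramachandran"] += 1
            rots = bundle.rotamers.get(res.name)
            if rots and ts.chi and any(c is not None for c in ts.chi):
                name, outlier = classify_rotamer(ts.chi, rots, rotamer_z)
                summ.rotamer_name = name
                summ.rotamer_class = "outlier" if outlier else "rotameric"
                if outlier:
                    summ.counts["rotamer-or-torsion"] += 1
            if ts.omega is not None and classify_omega(ts.omega) == "cis":
                summ.cis_peptide = True
            violations = check_chirality(res, bundle.chirality)
            if violations:
                summ.counts["chirality"] += len(violations)

    clashes = find_clashes(structure, bundle.vdw_radii, bundle.covalent_radii,
                           overlap_threshold=overlap_threshold,
                           include_symmetry=include_symmetry)
    for clash in clashes:
        for (res_key, _atom) in (clash.atom_a, clash.atom_b):
            if res_key in summaries:
                summaries[res_key].counts["clash"] += 1
    return GeometryValidationResult(summaries=summaries, clashes=clashes)


def entry_geometry_metrics(
    result: GeometryValidationResult,
    structure: StructureModel,
    include_hydrogens: bool = False,
) -> dict[str, Optional[float]]:
    """Entry-level roll-up: clashscore and outlier percentages."""
    n_atoms = structure.n_atoms(include_hydrogens=include_hydrogens)
    summaries = result.summaries
    rama_assessed = [s for s in summaries.values() if s.rama_class != "n/a"]
    rot_assessed = [s for s in summaries.values() if s.rotamer_class != "n/a"]
    return {
        "clashscore": clashscore(len(result.clashes), n_atoms),
        "rama_outlier_pct": (100.0 * sum(1 for s in rama_assessed if s.rama_class == "outlier")
                             / len(rama_assessed)) if rama_assessed else None,
        "rotamer_outlier_pct": (100.0 * sum(1 for s in rot_assessed if s.rotamer_class == "outlier")
                                / len(rot_assessed)) if rot_assessed else None,
    }
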