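"""Synthetic fixtures with known ground truth.

Generators here build every input the validators consume: ideal alpha-helical
peptides constructed from the same restraint dictionary the validator checks
against (so "ideal" means zero deviation by construction), structures with
planted defects and exact truth labels, toy ligands built at fragment-
statistics means, synthetic archives with documented metric families, and
observed maps derived from calculated maps plus seeded noise and deliberate
density erasure. Every generator is a pure function of its arguments,
including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .density import DensityMap, mask_indices
from .model import (
    Atom,
    Residue,
    ResidueKind,
    StructureModel,
    Method,
    UnitCell,
    compute_torsions,
    dihedral,
    bond_angle,
)
from .refdata import (
    ArchiveStats,
    ReferenceBundle,
    build_archive_stats,
    default_bundle,
    DEFAULT_BAND_EDGES,
)

__all__ = [
    "DistortionSpec",
    "make_helix_peptide",
    "inject_distortions",
    "make_toy_ligand",
    "make_xray_entry",
    "make_synthetic_archive",
    "make_obs_map",
    "make_shift_csv_text",
    "nerf",
]

HELIX_PHI = -57.0
HELIX_PSI = -47.0


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: place atom d given three reference
    atoms, the c-d bond length, the b-c-d angle and the a-b-c-d torsion."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(theta),
                   bond * math.sin(theta) * math.cos(tau),
                   bond * math.sin(theta) * math.sin(tau)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _rot_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                    angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    return (points - origin) @ R.T + origin


def _geom(bundle: ReferenceBundle, resname: str, key: str) -> float:
    entry = bundle.geometry.get(resname, key)
    if entry is None:
        raise KeyError(f"geometry dictionary lacks ({resname}, {key})")
    return entry[0]


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
              bond: float, angle_ncacb: float, angle_cbcac: float) -> np.ndarray:
    """CB position satisfying both flanking-angle targets with L chirality."""

    def cb_at(torsion: float) -> np.ndarray:
        return nerf(c, n, ca, bond, angle_ncacb, torsion)

    def angle_err(torsion: float) -> float:
        cb = cb_at(torsion)
        return bond_angle(cb, ca, c) - angle_cbcac

    solutions = []
    for lo, hi in ((1.0, 179.0), (-179.0, -1.0)):
        try:
            if angle_err(lo) * angle_err(hi) < 0:
                solutions.append(brentq(angle_err, lo, hi, xtol=1e-10))
        except ValueError:
            pass
    for t in solutions:
        cb = cb_at(t)
        if np.linalg.det(np.stack([n - ca, c - ca, cb - ca])) > 0:  # L config
            return cb
    raise RuntimeError("no L-configuration CB placement found")


def make_helix_peptide(
    n_res: int,
    sequence: Optional[Sequence[str]] = None,
    phi_psi: Optional[Sequence[tuple[float, float]]] = None,
    chi1: float = -65.0,
    bundle: Optional[ReferenceBundle] = None,
    chain_id: str = "A",
    b_iso: float = 20.0,
    cell_margin: float = 12.0,
) -> StructureModel:
    """Ideal-geometry alpha-helical peptide built from the restraint targets.

    Every covalent bond/angle sits exactly at its dictionary value, peptide
    bonds are trans, and default torsions are (phi, psi) = (-57, -47). The
    default sequence is poly-serine (a chi-bearing residue whose side chain
    the rotamer checks can classify); serine OG is placed at `chi1`."""
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    if sequence is None:
        sequence = ["SER"] * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length mismatch")
    if phi_psi is None:
        phi_psi = [(HELIX_PHI, HELIX_PSI)] * n_res
    if bundle is None:
        bundle = default_bundle()

    g = lambda rn, key: _geom(bundle, rn, key)
    link = lambda key: _geom(bundle, "PEPTIDE-LINK", key)

    residues: list[Residue] = []
    prev = None  # (N, CA, C) of previous residue
    for i, rn in enumerate(sequence):
        phi, psi = phi_psi[i]
        if prev is None:
            n_pos = np.zeros(3)
            ca_pos = n_pos + np.array([g(rn, "N-CA"), 0.0, 0.0])
            theta = math.radians(g(rn, "N-CA-C"))
            c_pos = ca_pos + g(rn, "CA-C") * np.array([-math.cos(theta), math.sin(theta), 0.0])
        else:
            pn, pca, pc = prev
            prev_psi = phi_psi[i - 1][1]
            n_pos = nerf(pn, pca, pc, link("C-N"), link("CA-C-N"), prev_psi)
            ca_pos = nerf(pca, pc, n_pos, g(rn, "N-CA"), link("C-N-CA"), 180.0)  # omega trans
            c_pos = nerf(pc, n_pos, ca_pos, g(rn, "CA-C"), g(rn, "N-CA-C"), phi)
        atoms = [Atom("N", "N", n_pos, 1.0, b_iso),
                 Atom("CA", "C", ca_pos, 1.0, b_iso),
                 Atom("C", "C", c_pos, 1.0, b_iso)]
        # carbonyl O anti to the next amide nitrogen: torsion N-CA-C-O = psi + 180
        o_pos = nerf(n_pos, ca_pos, c_pos, g(rn, "C-O"), g(rn, "CA-C-O"), psi + 180.0)
        atoms.append(Atom("O", "O", o_pos, 1.0, b_iso))
        if rn != "GLY":
            cb = _place_cb(n_pos, ca_pos, c_pos, g(rn, "CA-CB"),
                           g(rn, "N-CA-CB"), g(rn, "CB-CA-C"))
            atoms.append(Atom("CB", "C", cb, 1.0, b_iso))
            if rn == "SER":
                og = nerf(n_pos, ca_pos, cb, g(rn, "CB-OG"), g(rn, "CA-CB-OG"), chi1)
                atoms.append(Atom("OG", "O", og, 1.0, b_iso))
        residues.append(Residue(chain_id, i + 1, rn, atoms))
        prev = (n_pos, ca_pos, c_pos)

    structure = StructureModel(models=[{chain_id: residues}], method=Method.XRAY)
    structure.ensure_cell(margin=cell_margin)
    structure.cell_is_placeholder = False  # explicit P1 box cell
    return structure


# ---------------------------------------------------------------------------
# planted defects

@dataclass
class DistortionSpec:
    """Counts and magnitudes of planted defects; magnitudes in sigma units
    (for torsion-type defects the magnitude is ignored and a canonical
    outlier target is used)."""

    bond: int = 0
    angle: int = 0
    rama: int = 0
    rotamer: int = 0
    clash: int = 0
    chirality: int = 0
    magnitude: float = 6.0
    seed: int = 0

    def total(self) -> int:
        return self.bond + self.angle + self.rama + self.rotamer + self.clash + self.chirality


def _apply_bond(res: Residue, mag: float, sigma: float) -> None:
    c, o = res.get_atom("C"), res.get_atom("O")
    u = (o.pos - c.pos) / np.linalg.norm(o.pos - c.pos)
    o.pos = o.pos + mag * sigma * u


def _apply_angle(res: Residue, mag: float, sigma: float,
                 foreign_coords: Optional[np.ndarray] = None) -> None:
    """Rotate the carbonyl O in the CA-C-O plane by mag*sigma: only that
    angle changes. Of the two rotation senses (z = +mag or -mag, both
    outliers) the one keeping O clearer of surrounding atoms is used."""
    ca, c, o = (res.get_atom(n) for n in ("CA", "C", "O"))
    axis = np.cross(ca.pos - c.pos, o.pos - c.pos)

    def clearance(pos: np.ndarray) -> float:
        if foreign_coords is None or not foreign_coords.shape[0]:
            return 0.0
        return float(np.linalg.norm(foreign_coords - pos, axis=1).min())

    options = [_rot_about_axis(o.pos[None, :], c.pos, axis, s * mag * sigma)[0]
               for s in (+1.0, -1.0)]
    o.pos = max(options, key=clearance)


def _apply_rama(chain: list[Residue], idx: int,
                target: tuple[float, float] = (-80.0, 60.0)) -> None:
    """Drive (phi, psi) of residue idx to `target` by bond rotations that
    leave every covalent bond, angle and chi torsion untouched.

    Phi: rotate all of the residue except N (plus everything downstream)
    about the N-CA axis. Psi: rotate the carbonyl O (which stays anti to the
    next amide N) and everything downstream about the CA-C axis. The default
    target is a backbone conformation far outside the reference density yet
    sterically clean in a helical context."""
    res = chain[idx]
    n, ca, c = (res.get_atom(x) for x in ("N", "CA", "C"))
    pc = chain[idx - 1].get_atom("C")
    nn = chain[idx + 1].get_atom("N")
    downstream = [a for r in chain[idx + 1:] for a in r.atoms]

    cur_phi = dihedral(pc.pos, n.pos, ca.pos, c.pos)
    moving = [a for a in res.atoms if a.name != "N"] + downstream
    for a in moving:
        a.pos = _rot_about_axis(a.pos[None, :], ca.pos, ca.pos - n.pos,
                                target[0] - cur_phi)[0]

    cur_psi = dihedral(n.pos, ca.pos, c.pos, nn.pos)
    moving = [res.get_atom("O")] + downstream
    for a in moving:
        a.pos = _rot_about_axis(a.pos[None, :], ca.pos, c.pos - ca.pos,
                                target[1] - cur_psi)[0]


def _apply_rotamer(res: Residue, target_chi1: float = 120.0) -> None:
    n, ca, cb, og = (res.get_atom(x) for x in ("N", "CA", "CB", "OG"))
    current = dihedral(n.pos, ca.pos, cb.pos, og.pos)
    og.pos = _rot_about_axis(og.pos[None, :], cb.pos, cb.pos - ca.pos,
                             target_chi1 - current)[0]


def _apply_chirality(res: Residue) -> None:
    """Reflect the side chain through the N-CA-C plane: a D-residue with all
    bond lengths and angles preserved."""
    n, ca, c = (res.get_atom(x).pos for x in ("N", "CA", "C"))
    normal = np.cross(n - ca, c - ca)
    normal /= np.linalg.norm(normal)
    for a in res.atoms:
        if a.name in ("N", "CA", "C", "O"):
            continue
        v = a.pos - ca
        a.pos = a.pos - 2.0 * float(v @ normal) * normal


def _clash_water(res: Residue, foreign_coords: np.ndarray,
                 distance: float = 2.2, clearance: float = 3.0) -> Optional[Atom]:
    """Water oxygen 2.2 A from the residue's carbonyl O (a definite vdW
    clash) and clear of every atom outside the residue.

    Directions are sampled on a cone around the C=O axis (the straight
    extension points into the i+4 hydrogen-bond partner in a helix);
    None when no direction is clear."""
    c, o, ca = (res.get_atom(x) for x in ("C", "O", "CA"))
    u1 = (o.pos - c.pos) / np.linalg.norm(o.pos - c.pos)
    u2 = np.cross(c.pos - ca.pos, u1)
    u2 /= np.linalg.norm(u2)
    u3 = np.cross(u1, u2)
    best_pos, best_clear = None, -1.0
    for theta_deg in range(0, 91, 10):
        th = math.radians(theta_deg)
        for k in range(12):
            az = math.radians(30.0 * k)
            u = math.cos(th) * u1 + math.sin(th) * (math.cos(az) * u2 + math.sin(az) * u3)
            pos = o.pos + distance * u
            clear = (float(np.linalg.norm(foreign_coords - pos, axis=1).min())
                     if foreign_coords.shape[0] else math.inf)
            if clear > best_clear:
                best_pos, best_clear = pos, clear
            if theta_deg == 0:
                break
    if best_clear < clearance:
        return None
    return Atom("O", "O", best_pos, 1.0, 20.0)


def inject_distortions(
    structure: StructureModel,
    spec: DistortionSpec,
    bundle: Optional[ReferenceBundle] = None,
    verify: bool = True,
    max_attempts: int = 25,
) -> tuple[StructureModel, list[tuple[tuple[str, int, str], str]]]:
    """Plant the requested defects on disjoint residues; returns the distorted
    structure and the exact truth labels (residue key, defect type).

    Reproducible for a given seed. With `verify` (default) the planted
    structure is checked against the geometry validators and the residue
    assignment re-drawn if any unintended defect appears, so the truth
    labels are exactly the detectable defect set."""
    if bundle is None:
        bundle = default_bundle()
    chain_id = next(iter(structure.chains))
    chain_len = len(structure.chains[chain_id])
    interior = list(range(1, chain_len - 1))
    if spec.total() > len(interior):
        raise ValueError("more defects requested than available interior residues")

    rng = np.random.default_rng(spec.seed)
    last_error: Optional[str] = None
    # torsion (rama) defects go at chain-terminal interior positions, spaced
    # three residues apart, so the backbone rotations swing only a short
    # downstream segment and cannot fold the helix onto itself
    rama_idx = sorted(interior[-1 - 3 * k] for k in range(spec.rama))
    pool = [i for i in interior if i not in rama_idx]
    for attempt in range(max_attempts):
        out = structure.copy()
        chain = out.chains[chain_id]
        picks = rng.permutation(pool)
        cursor = 0
        truth: list[tuple[tuple[str, int, str], str]] = []

        def take(n: int) -> list[int]:
            nonlocal cursor
            sel = [int(i) for i in picks[cursor:cursor + n]]
            cursor += n
            return sel

        # rama first (rotates downstream atoms; the others are local edits)
        for i in rama_idx:
            _apply_rama(chain, i)
            truth.append((chain[i].key, "ramachandran"))
        for i in take(spec.bond):
            _apply_bond(chain[i], spec.magnitude, bundle.geometry.get(chain[i].name, "C-O")[1])
            truth.append((chain[i].key, "bond-length"))
        for i in take(spec.angle):
            foreign = np.array([a.pos for r, a in out.all_atoms()
                                if r.key != chain[i].key])
            _apply_angle(chain[i], spec.magnitude,
                         bundle.geometry.get(chain[i].name, "CA-C-O")[1], foreign)
            truth.append((chain[i].key, "bond-angle"))
        for i in take(spec.rotamer):
            _apply_rotamer(chain[i])
            truth.append((chain[i].key, "rotamer-or-torsion"))
        for i in take(spec.chirality):
            _apply_chirality(chain[i])
            truth.append((chain[i].key, "chirality"))
        clash_ok = True
        for w, i in enumerate(take(spec.clash)):
            foreign = np.array([a.pos for r, a in out.all_atoms()
                                if r.key != chain[i].key])
            water_o = _clash_water(chain[i], foreign)
            if water_o is None:
                clash_ok = False
                break
            water = Residue(chain_id, 9000 + w, "HOH", [water_o])
            chain.append(water)
            truth.append((chain[i].key, "clash"))
            truth.append((water.key, "clash"))
        if not clash_ok:
            last_error = "no clean water placement for a planted clash"
            continue

        if not verify:
            return out, truth
        ok, last_error = _verify_truth(out, truth, bundle)
        if ok:
            return out, truth
    raise RuntimeError(f"could not plant a clean defect set after {max_attempts} attempts: {last_error}")


def _verify_truth(structure: StructureModel,
                  truth: list[tuple[tuple[str, int, str], str]],
                  bundle: ReferenceBundle) -> tuple[bool, Optional[str]]:
    from .geometry import validate_geometry

    result = validate_geometry(structure, bundle)
    expected: dict[str, set] = {}
    for key, kind in truth:
        expected.setdefault(kind, set()).add(key)
    for criterion in ("bond-length", "bond-angle", "ramachandran",
                      "rotamer-or-torsion", "clash", "chirality"):
        found = {s.residue for s in result.values() if s.counts[criterion] > 0}
        if found != expected.get(criterion, set()):
            return False, f"{criterion}: planted {expected.get(criterion, set())}, detected {found}"
    return True, None


# ---------------------------------------------------------------------------
# toy ligand

_TOY_BONDS = [("C1", "C2"), ("C2", "C3"), ("C2", "O1")]


def make_toy_ligand(
    center: Optional[np.ndarray] = None,
    chain_id: str = "L",
    seq_num: int = 901,
    name: str = "TOY",
    bond_offset_sigmas: float = 0.0,
    bundle: Optional[ReferenceBundle] = None,
) -> tuple[Residue, list[tuple[str, str]]]:
    """A four-atom branched ligand built exactly at the fragment-statistics
    means; `bond_offset_sigmas` stretches the terminal C1-C2 bond to plant a
    geometry outlier. Returns (residue, connectivity)."""
    if bundle is None:
        bundle = default_bundle()
    stats = bundle.fragments
    b_cc = stats.get("C1-C3")
    b_co = stats.get("C3-O1")
    a_cc = stats.get("C1-C3-C1")
    a_co = stats.get("C1-C3-O1")
    if None in (b_cc, b_co, a_cc, a_co):
        raise KeyError("fragment statistics lack the toy-ligand keys")

    c2 = np.zeros(3)
    u1 = np.array([1.0, 0.0, 0.0])
    th = math.radians(a_cc[0])
    u3 = np.array([math.cos(th), math.sin(th), 0.0])
    # O1 direction with equal angles to both carbons
    target = math.cos(math.radians(a_co[0]))
    s = u1 + u3
    s /= np.linalg.norm(s)
    alpha = target / float(u1 @ s)
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha * float(s @ s)))
    u_o = alpha * s + beta * np.array([0.0, 0.0, 1.0])
    u_o /= np.linalg.norm(u_o)

    bond_c1 = b_cc[0] + bond_offset_sigmas * b_cc[1]
    atoms = [
        Atom("C1", "C", c2 + bond_c1 * u1, 1.0, 20.0),
        Atom("C2", "C", c2, 1.0, 20.0),
        Atom("C3", "C", c2 + b_cc[0] * u3, 1.0, 20.0),
        Atom("O1", "O", c2 + b_co[0] * u_o, 1.0, 20.0),
    ]
    if center is not None:
        shift = np.asarray(center, dtype=float) - c2
        for a in atoms:
            a.pos = a.pos + shift
    res = Residue(chain_id, seq_num, name, atoms)
    assert res.kind == ResidueKind.LIGAND
    return res, list(_TOY_BONDS)


def make_xray_entry(
    n_res: int = 16,
    seed: int = 0,
    with_ligand: bool = True,
    resolution: float = 2.0,
    n_unmodeled_tail: int = 0,
) -> StructureModel:
    """A crystal-style entry: helix (+ optional nearby toy ligand) in a P1
    box with a resolution. `n_unmodeled_tail` extends the sample sequence
    beyond the modeled residues (unmodeled = gray in reports)."""
    structure = make_helix_peptide(n_res)
    structure.resolution = resolution
    if with_ligand:
        chain = structure.chains["A"]
        mid = chain[n_res // 2]
        ca, cb = mid.get_atom("CA"), mid.get_atom("CB")
        u = (cb.pos - ca.pos) / np.linalg.norm(cb.pos - ca.pos)
        all_xyz = np.array([a.pos for _, a in structure.all_atoms()])
        cas = np.array([r.get_atom("CA").pos for r in chain])
        axis = cas[-1] - cas[0]
        axis /= np.linalg.norm(axis)
        placed = False
        best = None  # (n_neighbors, ligand)
        for blend in (0.0, 0.4, -0.4, 0.8, -0.8):
            direction = u + blend * axis
            direction /= np.linalg.norm(direction)
            for d in np.arange(3.8, 7.0, 0.1):
                ligand, _ = make_toy_ligand(center=cb.pos + d * direction)
                lig_xyz = np.array([a.pos for a in ligand.atoms])
                dist = np.linalg.norm(all_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
                if dist.min() < 3.1:  # clear of any vdW overlap at the 0.4 cut
                    continue
                per_res: dict = {}
                for (res, _a), row in zip(structure.all_atoms(), dist):
                    per_res[res.key] = min(per_res.get(res.key, 1e9), float(row.min()))
                n5 = sum(1 for v in per_res.values() if v <= 5.0)
                if n5 >= 2 and (best is None or n5 > best[0]):
                    best = (n5, ligand)
                break  # only the closest clearance-respecting d per direction
        if best is None:
            raise RuntimeError("could not place the toy ligand without contacts")
        structure.models[0]["L"] = [best[1]]
        # refresh bounding cell to cover the ligand
        structure.cell = None
        structure.ensure_cell(margin=12.0)
        structure.cell_is_placeholder = False
    if n_unmodeled_tail:
        structure.sample_sequence["A"] = (structure.sample_sequence["A"]
                                          + ["SER"] * n_unmodeled_tail)
    return structure


# ---------------------------------------------------------------------------
# synthetic archive

_ARCHIVE_RES_TYPES = ("ALA", "GLY", "SER", "LEU", "VAL")


def _band_index(resolution: float, edges=DEFAULT_BAND_EDGES) -> int:
    for i in range(len(edges) - 1):
        if edges[i] <= resolution < edges[i + 1]:
            return i
    return len(edges) - 2


def _rsr_band_mean(band: int) -> float:
    return 0.10 + 0.02 * band


_RSR_SD = 0.03


def make_synthetic_archive(
    n_entries: int,
    seed: int = 0,
    n_residues_per_entry: int = 30,
) -> tuple[ArchiveStats, dict]:
    """A desk-scale stand-in for the public archive.

    Entry resolutions are uniform on 1.0-3.5 A; metric values follow
    documented resolution-dependent families (normal/lognormal, clipped to
    physical ranges); per-residue RSR draws are normal with a band-dependent
    mean (0.10 + 0.02 per band) and sd 0.03. Returns the built ArchiveStats
    and a truth dict with the raw entries, RSR observations and generating
    parameters."""
    if n_entries < 10:
        raise ValueError("need at least 10 entries")
    rng = np.random.default_rng(seed)
    entries = []
    rsr_obs: list[tuple[str, float, float]] = []
    for _ in range(n_entries):
        res = float(rng.uniform(1.0, 3.5))
        entry = {
            "resolution": res,
            "method": "xray",
            "Rfree": float(np.clip(rng.normal(0.17 + 0.03 * res, 0.03), 0.10, 0.45)),
            "clashscore": float(rng.lognormal(math.log(1.0 + 2.0 * res), 0.5)),
            "rama_outlier_pct": float(max(0.0, rng.normal(0.1 + 0.3 * (res - 1.0), 0.3))),
            "rotamer_outlier_pct": float(max(0.0, rng.normal(0.5 + 1.0 * (res - 1.0), 0.8))),
            "rsrz_outlier_pct": float(max(0.0, rng.normal(1.0 + 1.5 * (res - 1.0), 1.5))),
        }
        entries.append(entry)
        band = _band_index(res)
        types = rng.choice(_ARCHIVE_RES_TYPES, size=n_residues_per_entry)
        vals = rng.normal(_rsr_band_mean(band), _RSR_SD, size=n_residues_per_entry)
        rsr_obs.extend((str(t), res, float(v)) for t, v in zip(types, vals))

    stats = build_archive_stats(entries, snapshot_date="synthetic",
                                rsr_observations=rsr_obs, min_band_n=10)
    truth = {
        "entries": entries,
        "rsr_observations": rsr_obs,
        "rsr_band_means": {b: _rsr_band_mean(b) for b in range(len(DEFAULT_BAND_EDGES) - 1)},
        "rsr_sd": _RSR_SD,
        "res_types": _ARCHIVE_RES_TYPES,
    }
    return stats, truth


# ---------------------------------------------------------------------------
# observed maps

def make_obs_map(
    calc: DensityMap,
    noise_sd: float = 0.0,
    erase_residues: Sequence[Residue] = (),
    seed: int = 0,
    erase_radius: float = 2.5,
) -> DensityMap:
    """Observed-map stand-in: calculated map plus seeded white noise, with the
    density of `erase_residues` wiped to background (known poor-fit truth)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = calc.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.values = out.values + rng.normal(0.0, noise_sd, size=out.values.shape)
    for res in erase_residues:
        coords = res.heavy_coords()
        if coords.shape[0]:
            mask = mask_indices(coords, out, erase_radius)
            out.values[mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# chemical-shift fixtures

def make_shift_csv_text(structure: StructureModel, seed: int = 0,
                        assigned_fraction: float = 1.0,
                        seq_offset: int = 0,
                        outlier_atoms: Sequence[tuple[str, int, str, float]] = (),
                        bundle: Optional[ReferenceBundle] = None) -> str:
    """CSV text of backbone H/N/CA/C/CB (+HA) shifts drawn at reference means.

    `seq_offset` shifts every sequence number (mapping-issue fixture);
    `outlier_atoms` entries (chain, seq, atom, z) plant Z-scored outliers.
    `assigned_fraction` keeps a seeded random subset of assignments."""
    if bundle is None:
        bundle = default_bundle()
    rng = np.random.default_rng(seed)
    planted = {(c, s, a): z for c, s, a, z in outlier_atoms}
    nucleus_of = {"H": "1H", "HA": "1H", "N": "15N", "CA": "13C", "CB": "13C", "C": "13C"}
    lines = ["chain,seq,res,atom,nucleus,ppm"]
    for res in structure.polymer_residues():
        if res.kind != ResidueKind.STANDARD_AA:
            continue
        for atom, nucleus in nucleus_of.items():
            if atom == "CB" and res.name == "GLY":
                continue
            keep = rng.random() <= assigned_fraction
            if not keep and (res.chain_id, res.seq_num, atom) not in planted:
                continue
            stats = bundle.shifts.get(res.name, atom, nucleus)
            if stats is None:
                continue
            mean, sd = stats
            z = planted.get((res.chain_id, res.seq_num, atom), 0.0)
            lines.append(f"{res.chain_id},{res.seq_num + seq_offset},{res.name},"
                         f"{atom},{nucleus},{mean + z * sd}")
    return "\n".join(lines) + "\n"
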