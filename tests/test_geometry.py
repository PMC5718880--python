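"""Geometry validators: covalent deviations, torsion classes, clashes,
chirality, ligand fragments."""

import math

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from strucval.geometry import (
    check_chirality,
    clashscore,
    classify_omega,
    classify_ramachandran,
    classify_rotamer,
    covalent_deviations,
    detect_cis_peptides,
    find_clashes,
    ligand_fragment_deviations,
    rama_class_of,
    rmsz,
    validate_geometry,
)
from strucval.model import (
    Atom,
    Method,
    Residue,
    StructureModel,
    UnitCell,
    bond_angle,
    rigid_transform,
)
from strucval.refdata import Rotamer
from strucval.synth import make_helix_peptide, make_toy_ligand


# ---------------------------------------------------------------------------
# covalent geometry

def test_ideal_residue_all_z_zero(helix10, bundle):
    chain = helix10.chains["A"]
    devs = covalent_deviations(chain[4], chain[5], bundle.geometry)
    assert len(devs) >= 10  # backbone + CB + OG + link entries
    assert max(abs(d.z) for d in devs) < 1e-9


def test_stretched_bond_z_exact(helix10, bundle):
    s = helix10.copy()
    res = s.chains["A"][4]
    n, ca = res.get_atom("N"), res.get_atom("CA")
    target, sigma = bundle.geometry.get("SER", "N-CA")
    u = (ca.pos - n.pos) / np.linalg.norm(ca.pos - n.pos)
    ca_shift = (target + 4.0 * sigma) - float(np.linalg.norm(ca.pos - n.pos))
    # move the whole residue tail rigidly so only this bond stretches
    for a in res.atoms:
        if a.name != "N":
            a.pos = a.pos + ca_shift * u
    devs = covalent_deviations(res, s.chains["A"][5], bundle.geometry)
    by_key = {d.key: d for d in devs}
    assert by_key["N-CA"].z == pytest.approx(4.0, abs=1e-9)
    assert by_key["N-CA"].is_outlier(4.0 - 1e-6)


def test_covalent_z_matches_brute_force(helix25, bundle, rng):
    """Randomly jitter atoms; engine z equals direct recomputation from
    raw distances/angles."""
    s = helix25.copy()
    for r in s.residues():
        for a in r.atoms:
            a.pos = a.pos + rng.normal(0, 0.05, 3)
    chain = s.chains["A"]
    for i in (2, 9, 17):
        res, nxt = chain[i], chain[i + 1]
        for d in covalent_deviations(res, nxt, bundle.geometry):
            names = d.key.split("-")
            # link entries take their trailing N/CA from the next residue
            coords = []
            for idx, nm in enumerate(names):
                a = res.get_atom(nm)
                if idx > 0 and nm in ("N", "CA") and d.key in ("C-N", "CA-C-N", "C-N-CA"):
                    a = nxt.get_atom(nm)
                coords.append(a.pos)
            if len(coords) == 2:
                obs = float(np.linalg.norm(coords[0] - coords[1]))
            else:
                obs = bond_angle(*coords)
            assert d.z == pytest.approx((obs - d.target) / d.sigma, abs=1e-9)


@pytest.mark.parametrize("zs,expected", [((0.0, 0.0, 0.0), 0.0),
                                         ((3.0, -4.0), math.sqrt(12.5))])
def test_rmsz_known_values(zs, expected):
    assert rmsz(zs) == pytest.approx(expected, abs=1e-12)


def test_rmsz_empty_is_undefined_and_matches_oracle(rng):
    assert rmsz([]) is None
    for _ in range(10):
        z = rng.normal(0, 2, rng.integers(1, 20))
        assert rmsz(z) == pytest.approx(float(np.sqrt((z ** 2).mean())), rel=1e-12)


# ---------------------------------------------------------------------------
# Ramachandran / rotamers / omega

def test_rama_canonical_classifications(bundle):
    assert classify_ramachandran(-57.0, -47.0, "general", bundle.ramachandran) == "favored"
    assert classify_ramachandran(58.0, -122.0, "general", bundle.ramachandran) == "outlier"


def test_rama_classification_matches_cumulative_mass_oracle(bundle):
    """For sampled bins of every class, classification agrees with a direct
    cumulative-mass computation over the grid."""
    ref = bundle.ramachandran
    for cls, g in ref.grids.items():
        n = g.shape[0]
        flat = g.ravel()
        for i in range(0, n, 7):
            for j in range(0, n, 11):
                phi = -180.0 + ref.bin_width * (i + 0.5)
                psi = -180.0 + ref.bin_width * (j + 0.5)
                mass = flat[flat >= g[i, j]].sum()
                expected = ("favored" if mass <= ref.favored_level
                            else "allowed" if mass <= ref.outlier_level
                            else "outlier")
                assert classify_ramachandran(phi, psi, cls, ref) == expected


def test_rama_class_assignment():
    ser = Residue("A", 1, "SER", [])
    gly = Residue("A", 2, "GLY", [])
    pro = Residue("A", 3, "PRO", [])
    assert rama_class_of(gly, ser) == "GLY"
    assert rama_class_of(pro, ser) == "PRO"
    assert rama_class_of(ser, pro) == "pre-PRO"
    assert rama_class_of(ser, ser) == "general"


def test_rotamer_classification():
    lib = [Rotamer("m", (-65.0,), (12.0,), 0.5), Rotamer("t", (180.0,), (12.0,), 0.3)]
    assert classify_rotamer([-65.0], lib) == ("m", False)   # exactly at mode
    assert classify_rotamer([-65.0 + 5 * 12.0], lib)[1]     # 5 sigma from m, far from t
    name, outlier = classify_rotamer([179.0], [Rotamer("w", (-179.0,), (12.0,), 1.0)])
    assert name == "w" and not outlier  # circular wrap: 2 degrees, not 358


def test_rotamer_no_chis_is_na():
    assert classify_rotamer([], [Rotamer("m", (-65.0,), (12.0,), 1.0)]) == (None, False)
    assert classify_rotamer([None], [Rotamer("m", (-65.0,), (12.0,), 1.0)]) == (None, False)


@pytest.mark.parametrize("omega,expected", [(180.0, "trans"), (-179.0, "trans"),
                                            (3.0, "cis"), (-29.9, "cis"),
                                            (90.0, "twisted"), (30.0, "twisted"),
                                            (150.0, "twisted")])
def test_omega_classification(omega, expected):
    assert classify_omega(omega) == expected


def test_detect_cis_peptides_list():
    assert detect_cis_peptides([180.0, 3.0, 90.0, None]) == ["trans", "cis", "twisted", None]


# ---------------------------------------------------------------------------
# chirality

def test_l_residue_has_no_chirality_violation(helix10, bundle):
    for res in helix10.residues():
        assert check_chirality(res, bundle.chirality) == []


def test_mirrored_residue_flagged(helix10, bundle):
    s = helix10.copy()
    for res in s.residues():
        for a in res.atoms:
            a.pos = a.pos * np.array([1.0, 1.0, -1.0])  # mirror the structure
    for res in s.residues():
        assert check_chirality(res, bundle.chirality) == ["CA"]


def test_chirality_sign_matches_determinant_oracle(helix10, bundle, rng):
    s = helix10.copy()
    for res in s.residues():
        for a in res.atoms:
            a.pos = a.pos + rng.normal(0, 0.05, 3)
        ca, n, c, cb = (res.get_atom(x).pos for x in ("CA", "N", "C", "CB"))
        det = np.linalg.det(np.stack([n - ca, c - ca, cb - ca]))
        assert (check_chirality(res, bundle.chirality) == []) == (det > 0)


# ---------------------------------------------------------------------------
# clashes

def _cloud_structure(coords, cell=None):
    atoms = [Atom(f"C{i}", "C", c) for i, c in enumerate(coords)]
    residues = [Residue("A", i + 1, "HOH", [a]) for i, a in enumerate(atoms)]
    return StructureModel(models=[{"A": residues}], cell=cell, method=Method.XRAY)


def test_two_atoms_no_clash_vs_clash(bundle):
    far = _cloud_structure([[0, 0, 0], [4.0, 0, 0]])
    far.ensure_cell()
    assert find_clashes(far, {"C": 1.7}, bundle.covalent_radii) == []
    near = _cloud_structure([[0, 0, 0], [2.9, 0, 0]])
    near.ensure_cell()
    clashes = find_clashes(near, {"C": 1.7}, bundle.covalent_radii, overlap_threshold=0.4)
    assert len(clashes) == 1
    assert clashes[0].overlap == pytest.approx(0.5, abs=1e-12)


def test_bonded_and_13_pairs_excluded(helix10, bundle):
    assert find_clashes(helix10, bundle.vdw_radii, bundle.covalent_radii) == []


def _all_pairs_clashes(structure, vdw, cov, threshold):
    """O(n^2) oracle for isolated single-atom residues (no bonds)."""
    pairs = structure.all_atoms(include_hydrogens=False)
    out = set()
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            ri, ai = pairs[i]
            rj, aj = pairs[j]
            d = float(np.linalg.norm(ai.pos - aj.pos))
            if vdw["C"] * 2 - d >= threshold:
                out.add(frozenset(((ri.key, ai.name), (rj.key, aj.name))))
    return out


@pytest.mark.parametrize("seed", range(4))
def test_clash_set_matches_all_pairs_oracle(seed, bundle):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 18, size=(200, 3))
    s = _cloud_structure(coords)
    s.ensure_cell()
    vdw = {"C": 1.7}
    got = {frozenset((c.atom_a, c.atom_b))
           for c in find_clashes(s, vdw, bundle.covalent_radii, include_symmetry=False)}
    assert got == _all_pairs_clashes(s, vdw, bundle.covalent_radii, 0.4)


def test_symmetry_clash_found_and_deduplicated(bundle):
    """Two atoms touching only across the periodic boundary of a P1 cell."""
    s = _cloud_structure([[0.5, 5.0, 5.0], [9.5, 5.0, 5.0]], cell=UnitCell(10, 10, 10))
    clashes = find_clashes(s, {"C": 1.7}, bundle.covalent_radii)
    sym = [c for c in clashes if c.symmetry]
    assert len(sym) == 1  # one contact, counted once despite two image routes
    assert sym[0].distance == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("n,k,expected", [(500, 0, 0.0), (500, 2, 4.0), (1000, 7, 7.0)])
def test_clashscore_formula(n, k, expected):
    assert clashscore(k, n) == pytest.approx(expected, abs=1e-12)


def test_clashscore_undefined_and_homogeneous():
    assert clashscore(1, 0) is None
    assert clashscore(6, 2000) == clashscore(3, 1000)  # duplication invariance


# ---------------------------------------------------------------------------
# ligand fragments

def test_toy_ligand_at_means_scores_zero(bundle):
    lig, bonds = make_toy_ligand(bundle=bundle)
    res = ligand_fragment_deviations(lig, bundle.fragments, bonds=bonds)
    assert res.n_unmatched == 0 and res.n_matched == 6
    assert res.bond_rmsz == pytest.approx(0.0, abs=1e-9)
    assert res.angle_rmsz == pytest.approx(0.0, abs=1e-9)


def test_planted_bond_outlier_detected(bundle):
    lig, bonds = make_toy_ligand(bond_offset_sigmas=6.0, bundle=bundle)
    res = ligand_fragment_deviations(lig, bundle.fragments, bonds=bonds)
    assert len(res.outliers(2.0)) == 1
    zs = sorted(abs(d.z) for d in res.deviations if d.kind == "bond")
    assert zs[-1] == pytest.approx(6.0, abs=1e-9)
    n_bonds = sum(1 for d in res.deviations if d.kind == "bond")
    assert res.bond_rmsz == pytest.approx(math.sqrt(sum(z * z for z in zs) / n_bonds))


def test_ligand_z_matches_recomputation(bundle, rng):
    lig, bonds = make_toy_ligand(bundle=bundle)
    for a in lig.atoms:
        a.pos = a.pos + rng.normal(0, 0.02, 3)
    res = ligand_fragment_deviations(lig, bundle.fragments, bonds=bonds)
    atoms = {a.name: a for a in lig.atoms}
    for d in res.deviations:
        names = d.key.split("|")[0].split("-")
        if d.kind == "bond":
            obs = float(np.linalg.norm(atoms[names[0]].pos - atoms[names[1]].pos))
        else:
            obs = bond_angle(*(atoms[nm].pos for nm in names))
        assert d.z == pytest.approx((obs - d.target) / d.sigma, abs=1e-9)


def test_unmatched_fragments_counted_not_scored(bundle):
    lig = Residue("L", 1, "UNK", [Atom("XE1", "SE", [0, 0, 0]),
                                  Atom("XE2", "SE", [2.4, 0, 0])])
    res = ligand_fragment_deviations(lig, bundle.fragments, bonds=[("XE1", "XE2")])
    assert res.n_matched == 0 and res.n_unmatched == 1
    assert res.bond_rmsz is None


# ---------------------------------------------------------------------------
# whole-structure properties

def test_classifications_rigid_invariant(bundle):
    from strucval.synth import DistortionSpec, inject_distortions
    s, truth = inject_distortions(make_helix_peptide(20),
                                  DistortionSpec(bond=1, rama=1, rotamer=1, seed=3),
                                  bundle=bundle)
    R = special_ortho_group.rvs(3, random_state=5)
    moved = rigid_transform(s, R, np.array([-4.0, 8.0, 2.0]))

    def summary_sets(result):
        return {crit: {x.residue for x in result.values() if x.counts[crit] > 0}
                for crit in ("bond-length", "ramachandran", "rotamer-or-torsion")}

    assert summary_sets(validate_geometry(s, bundle)) == \
        summary_sets(validate_geometry(moved, bundle))
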