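"""Structure model: I/O round trips, torsions, symmetry images, alt-locs."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from strucval.model import (
    Atom,
    Method,
    ParseError,
    Residue,
    StructureModel,
    SymOp,
    UnitCell,
    compute_torsions,
    dihedral,
    read_structure,
    rigid_transform,
    symmetry_images,
    write_structure,
)
from strucval.synth import HELIX_PHI, HELIX_PSI, make_helix_peptide


def _coords(s):
    return np.array([a.pos for _, a in s.all_atoms()])


def _identifiers(s):
    return [(r.chain_id, r.seq_num, r.ins_code, r.name, a.name)
            for r in s.residues() for a in r.effective_atoms()]


@pytest.mark.parametrize("fmt,tol", [("pdb", 1e-3), ("mmcif", 1e-3)])
def test_write_read_round_trip(helix10, tmp_path, fmt, tol):
    path = tmp_path / f"fixture.{ 'pdb' if fmt == 'pdb' else 'cif' }"
    write_structure(helix10, str(path), fmt)
    back = read_structure(str(path))
    assert np.abs(_coords(back) - _coords(helix10)).max() < tol
    assert _identifiers(back) == _identifiers(helix10)


def test_cross_format_parses_agree(helix10, tmp_path):
    """The same content read as PDB and as mmCIF yields the same structure."""
    p_pdb, p_cif = tmp_path / "a.pdb", tmp_path / "a.cif"
    write_structure(helix10, str(p_pdb), "pdb")
    write_structure(helix10, str(p_cif), "mmcif")
    s_pdb, s_cif = read_structure(str(p_pdb)), read_structure(str(p_cif))
    assert np.abs(_coords(s_pdb) - _coords(s_cif)).max() < 1e-3
    assert _identifiers(s_pdb) == _identifiers(s_cif)


def test_multi_model_ensemble(helix10, tmp_path):
    two = StructureModel(
        models=[helix10.models[0],
                {k: [r.copy() for r in v] for k, v in helix10.models[0].items()}],
        method=Method.NMR)
    path = tmp_path / "ens.pdb"
    write_structure(two, str(path))
    back = read_structure(str(path))
    assert len(back.models) == 2
    assert back.method == Method.NMR  # multi-MODEL defaults to NMR
    topo = [[(r.name, r.seq_num) for ch in m.values() for r in ch] for m in back.models]
    assert topo[0] == topo[1]


def test_malformed_input_raises():
    with pytest.raises(ParseError):
        read_structure("this is not\na coordinate file\n")


def test_helix_torsions(helix10):
    ts = compute_torsions(helix10.chains["A"])
    assert ts[0].phi is None and ts[-1].psi is None  # chain-end rule
    for t in ts[1:-1]:
        assert t.phi == pytest.approx(HELIX_PHI, abs=1e-6)
        assert t.psi == pytest.approx(HELIX_PSI, abs=1e-6)
    for t in ts[1:]:
        assert abs(t.omega) == pytest.approx(180.0, abs=1e-6)  # planar trans
    for t in ts:
        assert len(t.chi) == 1  # serine chi1
        assert t.chi[0] == pytest.approx(-65.0, abs=1e-6)


def test_collinear_dihedral_is_degenerate():
    p = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
    assert dihedral(*p) is None


def test_torsions_rigid_invariant(helix10):
    R = special_ortho_group.rvs(3, random_state=7)
    moved = rigid_transform(helix10, R, np.array([11.0, -3.0, 5.0]))
    t0 = compute_torsions(helix10.chains["A"])
    t1 = compute_torsions(moved.chains["A"])
    for a, b in zip(t0, t1):
        for x, y in ((a.phi, b.phi), (a.psi, b.psi), (a.omega, b.omega)):
            if x is not None:
                diff = abs(x - y) % 360.0
                assert min(diff, 360.0 - diff) < 1e-6


def test_altloc_highest_occupancy_wins():
    res = Residue("A", 1, "ALA", [
        Atom("CA", "C", [0, 0, 0], occupancy=0.4, alt_loc="A"),
        Atom("CA", "C", [1, 0, 0], occupancy=0.6, alt_loc="B"),
    ])
    assert res.get_atom("CA").pos[0] == 1.0
    tie = Residue("A", 1, "ALA", [
        Atom("CA", "C", [0, 0, 0], occupancy=0.5, alt_loc="B"),
        Atom("CA", "C", [1, 0, 0], occupancy=0.5, alt_loc="A"),
    ])
    assert tie.get_atom("CA").pos[0] == 1.0  # tie -> alphabetical alt_loc
    assert len(res.effective_atoms()) == 1


def test_symmetry_identity_only_gives_no_close_images():
    s = StructureModel(
        models=[{"A": [Residue("A", 1, "HOH", [Atom("O", "O", [20.0, 20.0, 20.0])])]}],
        cell=UnitCell(50, 50, 50), method=Method.XRAY)
    assert symmetry_images(s, 5.0) == []


def test_missing_cell_disables_symmetry():
    s = StructureModel(
        models=[{"A": [Residue("A", 1, "HOH", [Atom("O", "O", [0.0, 0.0, 0.0])])]}],
        method=Method.XRAY)
    s.ensure_cell()
    assert s.cell_is_placeholder
    assert symmetry_images(s, 5.0) == []


def _brute_force_images(structure, radius):
    orth = structure.cell.orth_matrix()
    frac = structure.cell.frac_matrix()
    pairs = structure.all_atoms(include_hydrogens=False)
    xyz = np.array([a.pos for _, a in pairs])
    fr = xyz @ frac.T
    found = set()
    for op in structure.sym_ops:
        fb = fr @ op.rot.T + op.trans
        fb -= np.floor(fb)
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    if op.is_identity and (i, j, k) == (0, 0, 0):
                        continue
                    ci = (fb + np.array([i, j, k])) @ orth.T
                    d = np.linalg.norm(ci[:, None, :] - xyz[None, :, :], axis=-1)
                    for ai in range(len(pairs)):
                        if d[ai].min() <= radius and np.linalg.norm(ci[ai] - xyz[ai]) > 1e-6:
                            found.add((ai, tuple(np.round(ci[ai], 6))))
    return found


@pytest.mark.parametrize("seed", range(5))
def test_symmetry_images_match_brute_force(seed):
    """k-d tree image search equals the 27-translate enumeration, with a
    two-operator (P-1 style) cell."""
    rng = np.random.default_rng(seed)
    ops = [SymOp(np.eye(3), np.zeros(3)),
           SymOp(-np.eye(3), np.array([0.5, 0.5, 0.5]))]
    atoms = [Atom(f"C{i}", "C", rng.uniform(0, 9, 3)) for i in range(20)]
    s = StructureModel(models=[{"A": [Residue("A", 1, "LIG", atoms)]}],
                       cell=UnitCell(9, 9, 9), sym_ops=ops, method=Method.XRAY)
    got = {(int(a.name[1:]), tuple(np.round(img.pos, 6)))
           for _, a, img, _, _ in symmetry_images(s, 3.0)}
    assert got == _brute_force_images(s, 3.0)
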