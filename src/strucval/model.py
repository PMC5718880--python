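"""Structure data model: atoms, residues, models, torsions and symmetry.

The in-memory model is deliberately small: chains of residues of atoms with
Cartesian coordinates in Angstroms, plus the unit cell, symmetry operators,
resolution and experimental method. File I/O (PDB and mmCIF) is delegated to
gemmi; only a documented subset of each format is interpreted (coordinates,
cell, symmetry, method, resolution, entity sequence).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKind",
    "StructureModel",
    "SymOp",
    "TorsionSet",
    "Method",
    "read_structure",
    "write_structure",
    "compute_torsions",
    "symmetry_images",
    "CHI_DEFINITIONS",
    "STANDARD_AA",
    "STANDARD_NT",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
STANDARD_NT = frozenset("A C G U DA DC DG DT DU".split())
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

# Side-chain torsion definitions (IUPAC): atom-name quadruples per chi.
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_KNOWN_ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA MN FE CO NI CU ZN SE BR I".split()
)


class ResidueKind(str, Enum):
    STANDARD_AA = "standard-aa"
    STANDARD_NT = "standard-nt"
    LIGAND = "ligand"
    NON_STANDARD_POLYMER = "non-standard-polymer"
    WATER = "water"


class Method(str, Enum):
    XRAY = "xray"
    NMR = "nmr"
    EM = "em"
    OTHER = "other"


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # Cartesian, Angstrom
    occupancy: float = 1.0
    b_iso: float = 20.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for atom {self.name}")
        if self.b_iso < 0:
            raise ValueError(f"negative b_iso for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occupancy,
                    self.b_iso, self.alt_loc)


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name."""
    stripped = atom_name.strip()
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "MN", "SE", "NA"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    ins_code: str = ""
    kind: Optional[ResidueKind] = None

    def __post_init__(self) -> None:
        if self.kind is None:
            self.kind = classify_residue(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.ins_code)

    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_num}{self.ins_code}"

    def get_atom(self, name: str) -> Optional[Atom]:
        """Return the atom with this name, resolving alt-locs to the
        highest-occupancy conformer (ties broken alphabetically)."""
        best: Optional[Atom] = None
        for a in self.atoms:
            if a.name != name:
                continue
            if best is None or (a.occupancy, _neg_alt(a.alt_loc)) > (best.occupancy, _neg_alt(best.alt_loc)):
                best = a
        return best

    def effective_atoms(self, include_hydrogens: bool = True) -> list[Atom]:
        """One atom per name after alt-loc resolution."""
        seen: dict[str, Atom] = {}
        for a in self.atoms:
            cur = seen.get(a.name)
            if cur is None or (a.occupancy, _neg_alt(a.alt_loc)) > (cur.occupancy, _neg_alt(cur.alt_loc)):
                seen[a.name] = a
        out = list(seen.values())
        if not include_hydrogens:
            out = [a for a in out if not a.is_hydrogen]
        return out

    def heavy_coords(self) -> np.ndarray:
        atoms = self.effective_atoms(include_hydrogens=False)
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in atoms])

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seq_num, self.name,
                       [a.copy() for a in self.atoms], self.ins_code, self.kind)


def _neg_alt(alt: str) -> tuple[int, str]:
    # sort key: higher occupancy wins; among ties the alphabetically first alt_loc
    return (0, "") if alt == "" else (-1, chr(255 - ord(alt[0])))


def classify_residue(name: str) -> ResidueKind:
    n = name.strip().upper()
    if n in STANDARD_AA:
        return ResidueKind.STANDARD_AA
    if n in STANDARD_NT:
        return ResidueKind.STANDARD_NT
    if n in WATER_NAMES:
        return ResidueKind.WATER
    return ResidueKind.LIGAND


@dataclass
class SymOp:
    """Symmetry operator in fractional coordinates: x' = R x + t."""
    rot: np.ndarray  # 3x3
    trans: np.ndarray  # 3

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float).reshape(3, 3)
        self.trans = np.asarray(self.trans, dtype=float).reshape(3)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot, np.eye(3)) and np.allclose(self.trans, 0.0)

    def __repr__(self) -> str:
        return f"SymOp(rot={self.rot.tolist()}, trans={self.trans.tolist()})"


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (columns are cell vectors)."""
        g = self.to_gemmi()
        return np.array(g.orth.mat.tolist())

    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix())


Chain = list[Residue]


@dataclass
class StructureModel:
    """One or more conformer models sharing a chain/residue topology."""

    models: list[dict[str, Chain]]  # model -> chain_id -> residues
    cell: Optional[UnitCell] = None
    sym_ops: list[SymOp] = field(default_factory=lambda: [SymOp(np.eye(3), np.zeros(3))])
    resolution: Optional[float] = None
    method: Method = Method.XRAY
    sample_sequence: dict[str, list[str]] = field(default_factory=dict)
    entry_id: str = "entry"
    cell_is_placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("StructureModel requires at least one model")
        if not any(op.is_identity for op in self.sym_ops):
            self.sym_ops.insert(0, SymOp(np.eye(3), np.zeros(3)))
        if not self.sample_sequence:
            self.sample_sequence = {
                cid: [r.name for r in residues]
                for cid, residues in self.models[0].items()
            }

    # -- convenience accessors over the first (representative) model --

    @property
    def chains(self) -> dict[str, Chain]:
        return self.models[0]

    def residues(self) -> Iterator[Residue]:
        for residues in self.models[0].values():
            yield from residues

    def polymer_residues(self) -> Iterator[Residue]:
        for r in self.residues():
            if r.kind in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT):
                yield r

    def ligand_residues(self) -> Iterator[Residue]:
        for r in self.residues():
            if r.kind == ResidueKind.LIGAND:
                yield r

    def all_atoms(self, include_hydrogens: bool = True) -> list[tuple[Residue, Atom]]:
        out = []
        for r in self.residues():
            for a in r.effective_atoms(include_hydrogens=include_hydrogens):
                out.append((r, a))
        return out

    def n_atoms(self, include_hydrogens: bool = False) -> int:
        return len(self.all_atoms(include_hydrogens=include_hydrogens))

    def ensure_cell(self, margin: float = 10.0) -> UnitCell:
        """Return the cell, synthesizing a P1 bounding box when absent.

        A synthesized cell disables symmetry checks (identity op only)."""
        if self.cell is not None:
            return self.cell
        coords = np.array([a.pos for _, a in self.all_atoms()])
        span = coords.max(axis=0) - coords.min(axis=0) + 2 * margin
        self.cell = UnitCell(*(float(s) for s in span))
        self.cell_is_placeholder = True
        self.sym_ops = [SymOp(np.eye(3), np.zeros(3))]
        return self.cell

    def copy(self) -> "StructureModel":
        return StructureModel(
            models=[{cid: [r.copy() for r in res] for cid, res in m.items()} for m in self.models],
            cell=None if self.cell is None else UnitCell(self.cell.a, self.cell.b, self.cell.c,
                                                         self.cell.alpha, self.cell.beta, self.cell.gamma),
            sym_ops=[SymOp(op.rot.copy(), op.trans.copy()) for op in self.sym_ops],
            resolution=self.resolution,
            method=self.method,
            sample_sequence={k: list(v) for k, v in self.sample_sequence.items()},
            entry_id=self.entry_id,
            cell_is_placeholder=self.cell_is_placeholder,
        )


@dataclass
class TorsionSet:
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None  # peptide bond preceding this residue
    chi: list[Optional[float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry primitives

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> Optional[float]:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180].

    Returns None for degenerate (collinear) configurations."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def compute_torsions(chain: Sequence[Residue]) -> list[TorsionSet]:
    """Backbone (phi, psi, omega) and side-chain chi angles for a chain.

    Angles with missing atoms are left undefined; omega(i) is the torsion of
    the peptide bond linking residue i-1 to residue i."""
    out: list[TorsionSet] = []
    for i, res in enumerate(chain):
        ts = TorsionSet()
        prev = chain[i - 1] if i > 0 else None
        nxt = chain[i + 1] if i + 1 < len(chain) else None
        n, ca, c = res.get_atom("N"), res.get_atom("CA"), res.get_atom("C")
        if prev is not None and _linked(prev, res):
            pc, pca = prev.get_atom("C"), prev.get_atom("CA")
            if pc is not None and None not in (n, ca, c):
                ts.phi = dihedral(pc.pos, n.pos, ca.pos, c.pos)
            if pca is not None and pc is not None and n is not None and ca is not None:
                ts.omega = dihedral(pca.pos, pc.pos, n.pos, ca.pos)
        if nxt is not None and _linked(res, nxt):
            nn = nxt.get_atom("N")
            if nn is not None and None not in (n, ca, c):
                ts.psi = dihedral(n.pos, ca.pos, c.pos, nn.pos)
        for quad in CHI_DEFINITIONS.get(res.name, []):
            atoms = [res.get_atom(nm) for nm in quad]
            ts.chi.append(None if any(a is None for a in atoms)
                          else dihedral(*(a.pos for a in atoms)))
        out.append(ts)
    return out


def _linked(r1: Residue, r2: Residue, max_cn: float = 2.0) -> bool:
    c, n = r1.get_atom("C"), r2.get_atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.pos - n.pos)) < max_cn


# ---------------------------------------------------------------------------
# symmetry

def symmetry_images(
    structure: StructureModel,
    radius: float,
    include_hydrogens: bool = False,
) -> list[tuple[Residue, Atom, Atom, SymOp, tuple[int, int, int]]]:
    """Symmetry- and lattice-translated atom images near the asymmetric unit.

    Returns tuples (source residue, source atom, image atom, op, lattice shift)
    for every non-identity copy whose image lies within `radius` of at least
    one asymmetric-unit atom. Atoms are wrapped into the unit cell before the
    3x3x3 lattice-translation block is applied, so any radius smaller than the
    shortest cell edge is covered.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if structure.cell is None or structure.cell_is_placeholder:
        return []
    cell = structure.cell
    orth = cell.orth_matrix()
    frac = cell.frac_matrix()

    pairs = structure.all_atoms(include_hydrogens=include_hydrogens)
    if not pairs:
        return []
    xyz = np.array([a.pos for _, a in pairs])
    fr = xyz @ frac.T

    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    images: list[tuple[Residue, Atom, Atom, SymOp, tuple[int, int, int]]] = []
    shifts = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for op in structure.sym_ops:
        f_img_base = fr @ op.rot.T + op.trans
        f_img_base -= np.floor(f_img_base)  # wrap into [0,1)
        for shift in shifts:
            if op.is_identity and shift == (0, 0, 0):
                continue
            f_img = f_img_base + np.array(shift, dtype=float)
            c_img = f_img @ orth.T
            if op.is_identity:
                # pure lattice translate of the wrapped AU; skip self-coincidence
                pass
            d, _ = tree.query(c_img, k=1)
            close = d <= radius
            # exclude exact self-images (op identity, wrapped position unchanged)
            for idx in np.nonzero(close)[0]:
                if np.linalg.norm(c_img[idx] - xyz[idx]) < 1e-6:
                    continue
                res, atom = pairs[idx]
                img = atom.copy()
                img.pos = c_img[idx]
                images.append((res, atom, img, op, shift))
    return images


# ---------------------------------------------------------------------------
# file I/O via gemmi

def read_structure(source: str | os.PathLike, format: Optional[str] = None,
                   method: Optional[Method] = None) -> StructureModel:
    """Read a PDB or mmCIF file (or literal text) into a StructureModel.

    `format` is 'pdb' or 'mmcif'; when omitted it is auto-detected from the
    filename extension or, for literal text, from the content."""
    text: Optional[str] = None
    path: Optional[str] = None
    s = os.fspath(source) if isinstance(source, os.PathLike) else source
    if "\n" in s or not os.path.exists(s):
        if "\n" not in s:
            raise ParseError(f"no such file: {s}")
        text = s
    else:
        path = s

    if format is None:
        probe = text if text is not None else open(path).read(4096)
        if path is not None and (path.endswith(".cif") or path.endswith(".mmcif")):
            format = "mmcif"
        elif path is not None and path.endswith(".pdb"):
            format = "pdb"
        elif probe.lstrip().startswith("data_") or "_atom_site." in probe:
            format = "mmcif"
        else:
            format = "pdb"

    try:
        if text is None:
            text = open(path).read()
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {format} input: {exc}") from exc

    sm = _from_gemmi(st, method=method)
    if path is not None:
        sm.entry_id = os.path.splitext(os.path.basename(path))[0].lower()
    return sm


def _from_gemmi(st: gemmi.Structure, method: Optional[Method] = None) -> StructureModel:
    st.setup_entities()
    models: list[dict[str, Chain]] = []
    for gm in st:
        chains: dict[str, Chain] = {}
        for gch in gm:
            residues: Chain = []
            for gres in gch:
                atoms = []
                for ga in gres:
                    el = ga.element.name if ga.element and ga.element.name != "X" else infer_element(ga.name)
                    atoms.append(Atom(
                        name=ga.name,
                        element=el,
                        pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(1.0, max(0.0, ga.occ)),
                        b_iso=max(0.0, ga.b_iso),
                        alt_loc="" if ga.altloc == "\x00" else ga.altloc,
                    ))
                residues.append(Residue(
                    chain_id=gch.name,
                    seq_num=gres.seqid.num,
                    ins_code="" if gres.seqid.icode in (" ", "\x00") else gres.seqid.icode,
                    name=gres.name,
                    atoms=atoms,
                ))
            if residues:
                chains[gch.name] = residues
        if chains:
            models.append(chains)
    if not models:
        raise ParseError("no atoms found in input")

    cell = None
    sym_ops = [SymOp(np.eye(3), np.zeros(3))]
    if st.cell and st.cell.a > 1.0 and not (st.cell.a == st.cell.b == st.cell.c == 1.0):
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
        sg = gemmi.SpaceGroup(st.spacegroup_hm) if st.spacegroup_hm else gemmi.SpaceGroup("P 1")
        sym_ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            trans = np.array(op.tran, dtype=float) / op.DEN
            sym_ops.append(SymOp(rot, trans))

    if method is None:
        method = Method.NMR if len(models) > 1 else Method.XRAY

    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    sample_seq: dict[str, list[str]] = {}
    for ent in st.entities:
        if ent.full_sequence:
            seq = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
            for sub in ent.subchains:
                for gch in st[0]:
                    for gres in gch:
                        if gres.subchain == sub:
                            sample_seq.setdefault(gch.name, seq)
                            break

    sm = StructureModel(models=models, cell=cell, sym_ops=sym_ops,
                        resolution=resolution, method=method,
                        sample_sequence=sample_seq,
                        entry_id=st.name.lower() or "entry")
    return sm


def to_gemmi(structure: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.entry_id
    if structure.cell is not None and not structure.cell_is_placeholder:
        c = structure.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        st.spacegroup_hm = "P 1"
    if structure.resolution:
        st.resolution = structure.resolution
    for mi, model in enumerate(structure.models, start=1):
        gm = gemmi.Model(mi)
        for cid, residues in model.items():
            gch = gemmi.Chain(cid)
            for res in residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.seq_num, res.ins_code or " ")
                gr.het_flag = "A" if res.kind in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT) else "H"
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.pos)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_iso
                    ga.altloc = a.alt_loc or "\x00"
                    gr.add_atom(ga)
                gch.add_residue(gr)
            gm.add_chain(gch)
        st.add_model(gm)
    return st


def write_structure(structure: StructureModel, path: str, format: Optional[str] = None) -> None:
    """Write the model as PDB or mmCIF (auto-detected from extension)."""
    if format is None:
        format = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
    st = to_gemmi(structure)
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def rigid_transform(structure: StructureModel, rot: np.ndarray, trans: np.ndarray) -> StructureModel:
    """Apply a rigid-body transform (Cartesian) to every atom of every model."""
    out = structure.copy()
    rot = np.asarray(rot, dtype=float)
    trans = np.asarray(trans, dtype=float)
    for model in out.models:
        for residues in model.values():
            for res in residues:
                for a in res.atoms:
                    a.pos = rot @ a.pos + trans
    return out
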