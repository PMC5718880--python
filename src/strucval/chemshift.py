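"""Chemical-shift list validation for NMR entries.

Each shift list is validated independently: records are mapped onto the
coordinate model (mapping problems are data, not errors), assignment
completeness is tabulated per nucleus and location class, and shifts are
compared against reference statistics — severe outliers (>30 SDs) usually
indicate spectral aliasing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import StructureModel, STANDARD_AA
from .refdata import ShiftRefStats

__all__ = [
    "ShiftRecord",
    "ShiftList",
    "MappingIssue",
    "MappingResult",
    "CompletenessCell",
    "ShiftOutlier",
    "read_shift_list",
    "map_shifts",
    "completeness",
    "flag_shift_outliers",
    "OUTLIER_Z",
    "SEVERE_Z",
]

OUTLIER_Z = 5.0
SEVERE_Z = 30.0

_NUCLEUS_BY_ELEMENT = {"H": "1H", "C": "13C", "N": "15N"}
SHIFT_CLASSES = ("backbone", "sidechain-aliphatic", "sidechain-aromatic")


@dataclass(frozen=True)
class ShiftRecord:
    chain: str
    seq_num: int
    res_name: str
    atom: str
    nucleus: str
    value: float


@dataclass
class ShiftList:
    list_id: str
    records: list[ShiftRecord]


@dataclass(frozen=True)
class MappingIssue:
    record: ShiftRecord
    code: str  # unmapped-residue | residue-name-mismatch | unknown-atom | nucleus-mismatch


@dataclass
class MappingResult:
    mapped: list[ShiftRecord]
    issues: list[MappingIssue]
    offset_candidate: Optional[int] = None


def read_shift_list(path: str, list_id: Optional[str] = None) -> ShiftList:
    """CSV columns: chain,seq,res,atom,nucleus,ppm."""
    df = pd.read_csv(path, dtype={"chain": str, "res": str, "atom": str, "nucleus": str})
    records = [ShiftRecord(str(r.chain), int(r.seq), str(r.res).upper(),
                           str(r.atom).upper(), str(r.nucleus), float(r.ppm))
               for r in df.itertuples()]
    return ShiftList(list_id or str(path), records)


def _expected_atom_names(res_name: str, expected_atoms: dict) -> set[str]:
    names: set[str] = set()
    for cls_table in expected_atoms.values():
        names.update(cls_table.get(res_name, []))
        names.update(cls_table.get("*", []))
    return names


def map_shifts(shifts: ShiftList, structure: StructureModel,
               expected_atoms: Optional[dict] = None) -> MappingResult:
    """Match each shift record to a model residue.

    A record maps when (chain, seq) exists in the model and the residue name
    agrees; the atom name must be a known atom for that residue type (from
    the expected-atom tables, which include hydrogens absent from the
    coordinates) or present in the model. A constant sequence offset between
    the shift list and the model is detected as the mode of per-record
    offsets that would repair unmapped records."""
    index = {(r.chain_id, r.seq_num): r for r in structure.residues()}
    by_chain: dict[str, dict[int, str]] = {}
    for r in structure.residues():
        by_chain.setdefault(r.chain_id, {})[r.seq_num] = r.name

    mapped: list[ShiftRecord] = []
    issues: list[MappingIssue] = []
    offsets: Counter = Counter()

    for rec in shifts.records:
        res = index.get((rec.chain, rec.seq_num))
        if res is None or res.name != rec.res_name:
            code = "unmapped-residue" if res is None else "residue-name-mismatch"
            issues.append(MappingIssue(rec, code))
            seqs = by_chain.get(rec.chain, {})
            for seq, name in seqs.items():
                if name == rec.res_name:
                    # shift-list numbering minus model numbering
                    offsets[rec.seq_num - seq] += 1
            continue
        known = set(a.name for a in res.atoms)
        if expected_atoms:
            known |= _expected_atom_names(res.name, expected_atoms)
        if rec.atom not in known and rec.atom.rstrip("123") not in known:
            issues.append(MappingIssue(rec, "unknown-atom"))
            continue
        elem = rec.atom[0]
        if _NUCLEUS_BY_ELEMENT.get(elem) != rec.nucleus:
            issues.append(MappingIssue(rec, "nucleus-mismatch"))
            continue
        mapped.append(rec)

    offset_candidate = None
    n_res_issues = sum(1 for i in issues if i.code in ("unmapped-residue", "residue-name-mismatch"))
    if offsets and n_res_issues:
        best, n_best = offsets.most_common(1)[0]
        if best != 0 and n_best >= max(2, n_res_issues // 2):
            offset_candidate = best
    return MappingResult(mapped=mapped, issues=issues, offset_candidate=offset_candidate)


@dataclass
class CompletenessCell:
    n_assigned: int
    n_expected: int

    @property
    def fraction(self) -> float:
        return self.n_assigned / self.n_expected if self.n_expected else 0.0


def completeness(mapped: list[ShiftRecord], structure: StructureModel,
                 expected_atoms: dict) -> dict[tuple[str, str], CompletenessCell]:
    """Assignment completeness per (location class, nucleus).

    Expected counts run over the sample sequence (all residues in the
    experimental sample, modeled or not)."""
    expected: Counter = Counter()
    assignable: dict[tuple[str, int, str], tuple[str, str]] = {}
    for chain_id, seq in structure.sample_sequence.items():
        for i, res_name in enumerate(seq, start=1):
            if res_name not in STANDARD_AA:
                continue
            for cls, table in expected_atoms.items():
                for atom in table.get(res_name, table.get("*", [])):
                    nucleus = _NUCLEUS_BY_ELEMENT.get(atom[0])
                    if nucleus is None:
                        continue
                    expected[(cls, nucleus)] += 1
                    assignable[(chain_id, i, atom)] = (cls, nucleus)

    assigned: Counter = Counter()
    seen: set = set()
    for rec in mapped:
        key = (rec.chain, rec.seq_num, rec.atom)
        alt = (rec.chain, rec.seq_num, rec.atom.rstrip("123"))
        k = key if key in assignable else (alt if alt in assignable else None)
        if k is None or k in seen:
            continue
        seen.add(k)
        assigned[assignable[k]] += 1

    return {key: CompletenessCell(assigned.get(key, 0), n)
            for key, n in sorted(expected.items())}


@dataclass
class ShiftOutlier:
    record: ShiftRecord
    z: float
    severe: bool


def flag_shift_outliers(mapped: list[ShiftRecord], ref: ShiftRefStats,
                        outlier_z: float = OUTLIER_Z,
                        severe_z: float = SEVERE_Z) -> tuple[list[ShiftOutlier], list[ShiftRecord]]:
    """Z-score each mapped shift; returns (outliers, records without reference).

    Outlier iff |z| > outlier_z; severe iff |z| > severe_z (the 30-SD rule)."""
    outliers: list[ShiftOutlier] = []
    skipped: list[ShiftRecord] = []
    for rec in mapped:
        stats = ref.get(rec.res_name, rec.atom, rec.nucleus)
        if stats is None:
            skipped.append(rec)
            continue
        mean, sd = stats
        z = (rec.value - mean) / sd
        if abs(z) > outlier_z:
            outliers.append(ShiftOutlier(rec, z, abs(z) > severe_z))
    return outliers, skipped
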