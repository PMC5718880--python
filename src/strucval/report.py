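"""Report assembly: residue color model, chain quality fractions, XML output.

The per-residue traffic-light model counts distinct outlier criteria:
green (none), yellow (one), orange (two), red (three or more); residues in
the experimental sample but absent from the model are gray, and modeled
residues ill-defined by an NMR ensemble are cyan. Poor fit to density
(RSRZ > 2) is a separate red-dot channel and never enters the color count.

Reports serialize to XML validated against the packaged XSD, plus a plain
text summary capped at five listed outliers per metric.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .density import LigandFit, ResidueFit
from .geometry import CRITERIA, LigandGeometryResult
from .percentile import SliderScores, SliderSet

__all__ = [
    "COLORS",
    "STAGES",
    "ResidueReportRecord",
    "LigandReportRecord",
    "ShiftSection",
    "ValidationReport",
    "residue_color",
    "chain_quality_fractions",
    "attach_rsrz_dots",
    "write_xml",
    "read_xml",
    "validate_xml",
    "write_summary",
]

COLORS = ("green", "yellow", "orange", "red", "gray", "cyan")
STAGES = ("preliminary", "confidential", "public")
_STAGE_WATERMARK = {"preliminary": "Preliminary", "confidential": "Confidential",
                    "public": "Public"}


def residue_color(outlier_types: set[str], modeled: bool, well_defined: bool) -> str:
    """Traffic-light color from the count of distinct outlier criteria."""
    if not modeled:
        return "gray"
    if not well_defined:
        return "cyan"
    n = len(outlier_types)
    if n == 0:
        return "green"
    if n == 1:
        return "yellow"
    if n == 2:
        return "orange"
    return "red"


@dataclass
class ResidueReportRecord:
    chain: str
    seq_num: int
    name: str
    modeled: bool = True
    well_defined: bool = True
    outlier_types: frozenset = frozenset()
    rsrz_dot: bool = False
    rsr: Optional[float] = None
    rsrz: Optional[float] = None
    rama_class: str = "n/a"
    rotamer_class: str = "n/a"
    cis_peptide: bool = False
    ins_code: str = ""

    @property
    def color(self) -> str:
        return residue_color(set(self.outlier_types), self.modeled, self.well_defined)


@dataclass
class LigandReportRecord:
    chain: str
    seq_num: int
    name: str
    bond_rmsz: Optional[float] = None
    angle_rmsz: Optional[float] = None
    n_matched: int = 0
    n_unmatched: int = 0
    n_geometry_outliers: int = 0
    rsr: Optional[float] = None
    n_neighbors: Optional[int] = None
    lldf: Optional[float] = None
    highlighted: bool = False
    lldf_reason: Optional[str] = None


@dataclass
class ShiftOutlierRecord:
    chain: str
    seq_num: int
    res_name: str
    atom: str
    nucleus: str
    value: float
    z: float
    severe: bool


@dataclass
class ShiftIssueRecord:
    code: str
    chain: str
    seq_num: int
    res_name: str
    atom: str


@dataclass
class ShiftSection:
    list_id: str
    completeness: dict[tuple[str, str], tuple[int, int]]  # (class, nucleus) -> (assigned, expected)
    outliers: list[ShiftOutlierRecord] = field(default_factory=list)
    issues: list[ShiftIssueRecord] = field(default_factory=list)
    offset_candidate: Optional[int] = None


@dataclass
class ValidationReport:
    entry_id: str
    method: str
    stage: str = "public"
    title: str = ""
    resolution: Optional[float] = None
    metrics: dict[str, float] = field(default_factory=dict)
    sliders: Optional[SliderSet] = None
    residues: list[ResidueReportRecord] = field(default_factory=list)
    ligands: list[LigandReportRecord] = field(default_factory=list)
    shift_sections: list[ShiftSection] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def chain_ids(self) -> list[str]:
        seen = dict.fromkeys(r.chain for r in self.residues)
        return list(seen)

    def chain_records(self, chain_id: str) -> list[ResidueReportRecord]:
        return [r for r in self.residues if r.chain == chain_id]


def chain_quality_fractions(records: list[ResidueReportRecord]) -> dict[str, float]:
    """Fraction of residues per color; denominator is the sample-sequence
    length (one record per sample residue, modeled or not)."""
    if not records:
        raise ValueError("chain has no residue records")
    counts = {c: 0 for c in COLORS}
    for r in records:
        counts[r.color] += 1
    n = len(records)
    return {c: counts[c] / n for c in COLORS}


def attach_rsrz_dots(records: list[ResidueReportRecord],
                     fits: dict[tuple[str, int, str], ResidueFit]) -> list[ResidueReportRecord]:
    """Set the red-dot channel from density fits; colors are untouched."""
    for rec in records:
        fit = fits.get((rec.chain, rec.seq_num, rec.ins_code))
        if fit is not None:
            rec.rsr = fit.rsr
            rec.rsrz = fit.rsrz
            rec.rsrz_dot = fit.outlier
    return records


# ---------------------------------------------------------------------------
# XML serialization

def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _set_opt(el: etree._Element, name: str, value) -> None:
    if value is not None:
        el.set(name, _fmt(value))


def write_xml(report: ValidationReport, path: Optional[str] = None) -> etree._ElementTree:
    """Serialize the report; the result validates against the packaged XSD."""
    root = etree.Element("validation_report")
    root.set("entry_id", report.entry_id)
    root.set("method", report.method)
    root.set("stage", report.stage)
    _set_opt(root, "title", report.title or None)
    _set_opt(root, "resolution", report.resolution)

    prov = etree.SubElement(root, "provenance")
    for name, version in sorted(report.provenance.items()):
        tool = etree.SubElement(prov, "tool")
        tool.set("name", name)
        tool.set("version", version)

    metrics = etree.SubElement(root, "entry_metrics")
    for key, value in sorted(report.metrics.items()):
        _set_opt(metrics, key, value)

    if report.sliders is not None:
        sliders = etree.SubElement(root, "sliders")
        for metric, s in sorted(report.sliders.sliders.items()):
            el = etree.SubElement(sliders, "slider")
            el.set("metric", metric)
            el.set("value", _fmt(s.value))
            el.set("absolute", _fmt(s.absolute))
            el.set("relative", _fmt(s.relative))
            el.set("pool", str(s.pool_size))
            _set_opt(el, "window", s.window)
        for metric, reason in sorted(report.sliders.omitted.items()):
            el = etree.SubElement(sliders, "omitted")
            el.set("metric", metric)
            el.set("reason", reason)

    chains = etree.SubElement(root, "chains")
    for cid in report.chain_ids():
        fracs = chain_quality_fractions(report.chain_records(cid))
        el = etree.SubElement(chains, "chain")
        el.set("id", cid)
        for color in COLORS:
            el.set(color, _fmt(fracs[color]))

    residues = etree.SubElement(root, "residues")
    for r in report.residues:
        el = etree.SubElement(residues, "residue")
        el.set("chain", r.chain)
        el.set("seq", str(r.seq_num))
        _set_opt(el, "ins", r.ins_code or None)
        el.set("name", r.name)
        el.set("modeled", _fmt(r.modeled))
        el.set("well_defined", _fmt(r.well_defined))
        el.set("color", r.color)
        el.set("outlier_types", " ".join(sorted(r.outlier_types)))
        el.set("rsrz_dot", _fmt(r.rsrz_dot))
        _set_opt(el, "rsr", r.rsr)
        _set_opt(el, "rsrz", r.rsrz)
        el.set("rama", r.rama_class)
        el.set("rotamer", r.rotamer_class)
        el.set("cis", _fmt(r.cis_peptide))

    ligands = etree.SubElement(root, "ligands")
    for lig in report.ligands:
        el = etree.SubElement(ligands, "ligand")
        el.set("chain", lig.chain)
        el.set("seq", str(lig.seq_num))
        el.set("name", lig.name)
        _set_opt(el, "bond_rmsz", lig.bond_rmsz)
        _set_opt(el, "angle_rmsz", lig.angle_rmsz)
        el.set("n_matched", str(lig.n_matched))
        el.set("n_unmatched", str(lig.n_unmatched))
        el.set("n_geometry_outliers", str(lig.n_geometry_outliers))
        _set_opt(el, "rsr", lig.rsr)
        _set_opt(el, "n_neighbors", lig.n_neighbors)
        _set_opt(el, "lldf", lig.lldf)
        el.set("highlighted", _fmt(lig.highlighted))
        _set_opt(el, "lldf_reason", lig.lldf_reason)

    if report.shift_sections:
        shifts = etree.SubElement(root, "chemical_shifts")
        for sec in report.shift_sections:
            sl = etree.SubElement(shifts, "shift_list")
            sl.set("id", sec.list_id)
            _set_opt(sl, "offset_candidate", sec.offset_candidate)
            for (cls, nucleus), (assigned, expected) in sorted(sec.completeness.items()):
                cel = etree.SubElement(sl, "completeness")
                cel.set("class", cls)
                cel.set("nucleus", nucleus)
                cel.set("assigned", str(assigned))
                cel.set("expected", str(expected))
                cel.set("fraction", _fmt(assigned / expected if expected else 0.0))
            for o in sec.outliers:
                oel = etree.SubElement(sl, "outlier")
                oel.set("chain", o.chain)
                oel.set("seq", str(o.seq_num))
                oel.set("res", o.res_name)
                oel.set("atom", o.atom)
                oel.set("nucleus", o.nucleus)
                oel.set("value", _fmt(o.value))
                oel.set("z", _fmt(o.z))
                oel.set("severe", _fmt(o.severe))
            for i in sec.issues:
                iel = etree.SubElement(sl, "issue")
                iel.set("code", i.code)
                iel.set("chain", i.chain)
                iel.set("seq", str(i.seq_num))
                iel.set("res", i.res_name)
                iel.set("atom", i.atom)

    tree = etree.ElementTree(root)
    validate_xml(tree)
    if path is not None:
        tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
    return tree


def _schema() -> etree.XMLSchema:
    ref = importlib.resources.files("strucval") / "data" / "validation_report.xsd"
    with importlib.resources.as_file(ref) as p:
        return etree.XMLSchema(etree.parse(str(p)))


def validate_xml(tree: etree._ElementTree) -> None:
    schema = _schema()
    if not schema.validate(tree):
        raise AssertionError(f"report XML violates schema: {schema.error_log}")


def _opt_float(el: etree._Element, name: str) -> Optional[float]:
    v = el.get(name)
    return None if v is None else float(v)


def _bool(s: str) -> bool:
    return s == "true"


def read_xml(source: str) -> ValidationReport:
    """Parse a report XML file (or literal XML text) back into objects."""
    if "<" in source:
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(str(source)).getroot()
    tree = etree.ElementTree(root)
    validate_xml(tree)

    report = ValidationReport(
        entry_id=root.get("entry_id"),
        method=root.get("method"),
        stage=root.get("stage"),
        title=root.get("title", ""),
        resolution=_opt_float(root, "resolution"),
    )
    prov = root.find("provenance")
    if prov is not None:
        report.provenance = {t.get("name"): t.get("version") for t in prov.findall("tool")}
    metrics = root.find("entry_metrics")
    if metrics is not None:
        report.metrics = {k: float(v) for k, v in metrics.attrib.items()}
    sliders_el = root.find("sliders")
    if sliders_el is not None:
        sliders = {}
        omitted = {}
        for el in sliders_el.findall("slider"):
            sliders[el.get("metric")] = SliderScores(
                metric=el.get("metric"), value=float(el.get("value")),
                absolute=float(el.get("absolute")), relative=float(el.get("relative")),
                pool_size=int(el.get("pool")), window=_opt_float(el, "window"))
        for el in sliders_el.findall("omitted"):
            omitted[el.get("metric")] = el.get("reason")
        report.sliders = SliderSet(sliders=sliders, omitted=omitted)
    for el in root.find("residues").findall("residue"):
        report.residues.append(ResidueReportRecord(
            chain=el.get("chain"), seq_num=int(el.get("seq")), name=el.get("name"),
            ins_code=el.get("ins", ""),
            modeled=_bool(el.get("modeled")), well_defined=_bool(el.get("well_defined")),
            outlier_types=frozenset(el.get("outlier_types").split()) if el.get("outlier_types") else frozenset(),
            rsrz_dot=_bool(el.get("rsrz_dot")),
            rsr=_opt_float(el, "rsr"), rsrz=_opt_float(el, "rsrz"),
            rama_class=el.get("rama"), rotamer_class=el.get("rotamer"),
            cis_peptide=_bool(el.get("cis"))))
    lig_el = root.find("ligands")
    if lig_el is not None:
        for el in lig_el.findall("ligand"):
            report.ligands.append(LigandReportRecord(
                chain=el.get("chain"), seq_num=int(el.get("seq")), name=el.get("name"),
                bond_rmsz=_opt_float(el, "bond_rmsz"), angle_rmsz=_opt_float(el, "angle_rmsz"),
                n_matched=int(el.get("n_matched")), n_unmatched=int(el.get("n_unmatched")),
                n_geometry_outliers=int(el.get("n_geometry_outliers")),
                rsr=_opt_float(el, "rsr"),
                n_neighbors=None if el.get("n_neighbors") is None else int(el.get("n_neighbors")),
                lldf=_opt_float(el, "lldf"), highlighted=_bool(el.get("highlighted")),
                lldf_reason=el.get("lldf_reason")))
    cs = root.find("chemical_shifts")
    if cs is not None:
        for sl in cs.findall("shift_list"):
            sec = ShiftSection(
                list_id=sl.get("id"),
                completeness={(c.get("class"), c.get("nucleus")):
                              (int(c.get("assigned")), int(c.get("expected")))
                              for c in sl.findall("completeness")},
                offset_candidate=None if sl.get("offset_candidate") is None
                else int(sl.get("offset_candidate")))
            for o in sl.findall("outlier"):
                sec.outliers.append(ShiftOutlierRecord(
                    chain=o.get("chain"), seq_num=int(o.get("seq")), res_name=o.get("res"),
                    atom=o.get("atom"), nucleus=o.get("nucleus"),
                    value=float(o.get("value")), z=float(o.get("z")),
                    severe=_bool(o.get("severe"))))
            for i in sl.findall("issue"):
                sec.issues.append(ShiftIssueRecord(
                    code=i.get("code"), chain=i.get("chain"), seq_num=int(i.get("seq")),
                    res_name=i.get("res"), atom=i.get("atom")))
            report.shift_sections.append(sec)
    return report


# ---------------------------------------------------------------------------
# text summary

_SUMMARY_MAX = 5


def _outlier_section(lines: list[str], title: str, items: list[str]) -> None:
    lines.append(f"{title}: {len(items)}")
    for item in items[:_SUMMARY_MAX]:
        lines.append(f"  - {item}")
    if len(items) > _SUMMARY_MAX:
        lines.append(f"  ... and {len(items) - _SUMMARY_MAX} more")


def write_summary(report: ValidationReport, path: Optional[str] = None) -> str:
    """Plain-text executive summary: at most five listed outliers per metric."""
    lines = [
        f"Validation summary for entry {report.entry_id}",
        f"Report stage: {_STAGE_WATERMARK[report.stage]}",
        f"Method: {report.method}"
        + (f"   Resolution: {report.resolution:.2f} A" if report.resolution else ""),
        "",
    ]
    for key in sorted(report.metrics):
        lines.append(f"{key}: {report.metrics[key]:.3f}")
    if report.sliders is not None and report.sliders.sliders:
        lines.append("")
        lines.append("Percentile ranks (absolute / relative):")
        for metric, s in sorted(report.sliders.sliders.items()):
            lines.append(f"  {metric}: {s.absolute:.1f} / {s.relative:.1f} (pool {s.pool_size})")
    lines.append("")

    def residues_with(criterion: str) -> list[str]:
        return [f"{r.chain}:{r.name}{r.seq_num}" for r in report.residues
                if criterion in r.outlier_types]

    titles = {"bond-length": "Bond-length outliers", "bond-angle": "Bond-angle outliers",
              "ramachandran": "Ramachandran outliers", "rotamer-or-torsion": "Rotamer outliers",
              "clash": "Clashing residues", "chirality": "Chirality errors"}
    for criterion in CRITERIA:
        _outlier_section(lines, titles[criterion], residues_with(criterion))
    _outlier_section(lines, "Poor density fit (RSRZ > 2)",
                     [f"{r.chain}:{r.name}{r.seq_num}" for r in report.residues if r.rsrz_dot])
    if report.ligands:
        _outlier_section(lines, "Ligands highlighted by LLDF",
                         [f"{l.chain}:{l.name}{l.seq_num}" for l in report.ligands if l.highlighted])
    for sec in report.shift_sections:
        _outlier_section(lines, f"Severe chemical-shift outliers ({sec.list_id})",
                         [f"{o.chain}:{o.res_name}{o.seq_num}.{o.atom}"
                          for o in sec.outliers if o.severe])
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
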