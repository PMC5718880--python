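"""End-to-end validation: run every applicable check and assemble the report.

This is the function behind the command-line `strucval validate`: geometry
checks always run; density fit runs when observed and calculated maps are
supplied (RSRZ additionally needs archive statistics and a resolution);
R factors need a reflection list; chemical-shift sections need shift lists.
Skipped checks are recorded with a reason.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from . import __version__
from .chemshift import (
    ShiftList,
    completeness,
    flag_shift_outliers,
    map_shifts,
)
from .density import (
    DensityMap,
    ReflectionSet,
    lldf,
    r_factors,
    residue_fits,
)
from .geometry import (
    LIGAND_OUTLIER_Z,
    entry_geometry_metrics,
    ligand_fragment_deviations,
    validate_geometry,
)
from .model import ResidueKind, StructureModel
from .percentile import slider_panel
from .refdata import ReferenceBundle, default_bundle
from .report import (
    LigandReportRecord,
    ResidueReportRecord,
    ShiftIssueRecord,
    ShiftOutlierRecord,
    ShiftSection,
    ValidationReport,
    attach_rsrz_dots,
)

log = logging.getLogger("strucval")

__all__ = ["validate_entry"]


def validate_entry(
    structure: StructureModel,
    bundle: Optional[ReferenceBundle] = None,
    map_obs: Optional[DensityMap] = None,
    map_calc: Optional[DensityMap] = None,
    reflections: Optional[ReflectionSet] = None,
    shift_lists: Sequence[ShiftList] = (),
    well_defined: Optional[dict[tuple[str, int, str], bool]] = None,
    stage: str = "public",
    title: str = "",
) -> ValidationReport:
    """Validate one entry and return the assembled report."""
    if bundle is None:
        bundle = default_bundle()
    archive = bundle.archive

    geo = validate_geometry(structure, bundle)
    metrics = {k: v for k, v in entry_geometry_metrics(geo, structure).items()
               if v is not None}

    fits = None
    if map_obs is not None and map_calc is not None:
        stats = archive if (archive is not None and archive.rsr_norm
                            and structure.resolution is not None) else None
        if stats is None:
            log.info("density fit: RSR only (no archive normalization available)")
        fits = residue_fits(structure, map_obs, map_calc, stats)
        with_z = [f for f in fits.values() if f.rsrz is not None]
        if with_z:
            metrics["rsrz_outlier_pct"] = (100.0 * sum(1 for f in with_z if f.outlier)
                                           / len(with_z))
    else:
        log.info("density fit skipped: maps not provided")

    if reflections is not None:
        r_work, r_free = r_factors(reflections)
        if r_work is not None:
            metrics["Rwork"] = r_work
        if r_free is not None:
            metrics["Rfree"] = r_free
    else:
        log.info("R factors skipped: reflection list not provided")

    report = ValidationReport(
        entry_id=structure.entry_id,
        method=structure.method.value,
        stage=stage,
        title=title,
        resolution=structure.resolution,
        metrics=metrics,
        provenance={"strucval": __version__,
                    **{k: v for k, v in bundle.versions.items()}},
    )

    # per-residue records over the sample sequence (unmodeled residues -> gray)
    modeled = {r.key: r for r in structure.residues()}
    for chain_id, seq in structure.sample_sequence.items():
        chain_residues = {r.seq_num: r for r in structure.chains.get(chain_id, [])}
        for pos, res_name in enumerate(seq, start=1):
            res = chain_residues.get(pos)
            if res is None:
                report.residues.append(ResidueReportRecord(
                    chain=chain_id, seq_num=pos, name=res_name, modeled=False))
                continue
            if res.kind in (ResidueKind.LIGAND, ResidueKind.WATER):
                continue  # ligands get their own records; waters are not reported
            summ = geo.summaries[res.key]
            wd = True if well_defined is None else well_defined.get(res.key, True)
            report.residues.append(ResidueReportRecord(
                chain=chain_id, seq_num=res.seq_num, name=res.name,
                ins_code=res.ins_code, modeled=True, well_defined=wd,
                outlier_types=frozenset(summ.outlier_types),
                rama_class=summ.rama_class, rotamer_class=summ.rotamer_class,
                cis_peptide=summ.cis_peptide))
    if fits is not None:
        attach_rsrz_dots(report.residues, fits)

    rsr_table = ({k: f.rsr for k, f in fits.items() if f.rsr is not None}
                 if fits is not None else {})
    for lig in structure.ligand_residues():
        geom = ligand_fragment_deviations(lig, bundle.fragments,
                                          cov_radii=bundle.covalent_radii)
        rec = LigandReportRecord(
            chain=lig.chain_id, seq_num=lig.seq_num, name=lig.name,
            bond_rmsz=geom.bond_rmsz, angle_rmsz=geom.angle_rmsz,
            n_matched=geom.n_matched, n_unmatched=geom.n_unmatched,
            n_geometry_outliers=len(geom.outliers(LIGAND_OUTLIER_Z)))
        if fits is not None:
            fit = lldf(lig, rsr_table, structure)
            rec.rsr = fit.rsr
            rec.n_neighbors = fit.n_neighbors
            rec.lldf = fit.lldf
            rec.highlighted = fit.highlighted
            rec.lldf_reason = fit.reason
        report.ligands.append(rec)

    for shifts in shift_lists:
        mapping = map_shifts(shifts, structure, bundle.expected_atoms)
        table = completeness(mapping.mapped, structure, bundle.expected_atoms)
        outliers, _skipped = flag_shift_outliers(mapping.mapped, bundle.shifts)
        report.shift_sections.append(ShiftSection(
            list_id=shifts.list_id,
            completeness={k: (c.n_assigned, c.n_expected) for k, c in table.items()},
            outliers=[ShiftOutlierRecord(o.record.chain, o.record.seq_num,
                                         o.record.res_name, o.record.atom,
                                         o.record.nucleus, o.record.value,
                                         o.z, o.severe)
                      for o in outliers],
            issues=[ShiftIssueRecord(i.code, i.record.chain, i.record.seq_num,
                                     i.record.res_name, i.record.atom)
                    for i in mapping.issues],
            offset_candidate=mapping.offset_candidate))

    if archive is not None and archive.metrics:
        report.sliders = slider_panel(metrics, archive,
                                      method=structure.method.value,
                                      resolution=structure.resolution)
    else:
        log.info("sliders skipped: no archive metric distributions")
    return report
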