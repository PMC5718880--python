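"""Report assembly: color model, chain fractions, XML schema, summary."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strucval.density import ResidueFit, synthesize_map
from strucval.geometry import CRITERIA, validate_geometry
from strucval.pipeline import validate_entry
from strucval.refdata import default_bundle
from strucval.report import (
    ResidueReportRecord,
    ValidationReport,
    attach_rsrz_dots,
    chain_quality_fractions,
    read_xml,
    residue_color,
    write_summary,
    write_xml,
)
from strucval.synth import (
    DistortionSpec,
    inject_distortions,
    make_helix_peptide,
    make_obs_map,
    make_synthetic_archive,
    make_xray_entry,
)


# ---------------------------------------------------------------------------
# color model

def test_color_mapping_exhaustive():
    """All 2^6 outlier-type subsets x modeled/well-defined combinations."""
    for r in range(len(CRITERIA) + 1):
        for subset in itertools.combinations(CRITERIA, r):
            types = set(subset)
            n = len(types)
            expected = "green" if n == 0 else "yellow" if n == 1 else \
                       "orange" if n == 2 else "red"
            assert residue_color(types, True, True) == expected
            assert residue_color(types, False, True) == "gray"
            assert residue_color(types, False, False) == "gray"
            assert residue_color(types, True, False) == "cyan"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.sets(st.sampled_from(CRITERIA)))
def test_color_depends_only_on_cardinality(types):
    by_count = {0: "green", 1: "yellow", 2: "orange"}
    expected = by_count.get(len(types), "red")
    assert residue_color(types, True, True) == expected


def _rec(i, color_source=frozenset(), modeled=True, well=True):
    return ResidueReportRecord(chain="A", seq_num=i, name="SER", modeled=modeled,
                               well_defined=well, outlier_types=frozenset(color_source))


def test_chain_fractions_examples():
    all_green = [_rec(i) for i in range(10)]
    f = chain_quality_fractions(all_green)
    assert f["green"] == 1.0 and sum(f.values()) == pytest.approx(1.0)
    mixed = [_rec(i) for i in range(8)] + [_rec(9, modeled=False), _rec(10, modeled=False)]
    f = chain_quality_fractions(mixed)
    assert f["green"] == pytest.approx(0.8)
    assert f["gray"] == pytest.approx(0.2)


def test_chain_fractions_match_counting_oracle(rng):
    colors = {"green": (frozenset(), True, True),
              "yellow": (frozenset({"clash"}), True, True),
              "orange": (frozenset({"clash", "bond-length"}), True, True),
              "red": (frozenset(CRITERIA[:3]), True, True),
              "gray": (frozenset(), False, True),
              "cyan": (frozenset(), True, False)}
    for _ in range(20):
        labels = rng.choice(list(colors), size=30)
        recs = [ResidueReportRecord("A", i, "SER", modeled=colors[c][1],
                                    well_defined=colors[c][2], outlier_types=colors[c][0])
                for i, c in enumerate(labels)]
        f = chain_quality_fractions(recs)
        for color in colors:
            assert f[color] == pytest.approx(np.mean(labels == color))
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)


def test_rsrz_dot_separate_from_color():
    recs = [_rec(1)]
    fits = {("A", 1, ""): ResidueFit(rsr=0.2, rsrz=2.5, outlier=True)}
    attach_rsrz_dots(recs, fits)
    assert recs[0].rsrz_dot and recs[0].color == "green"  # dot never colors
    recs2 = [_rec(2)]
    attach_rsrz_dots(recs2, {("A", 2, ""): ResidueFit(rsr=0.2, rsrz=1.9, outlier=False)})
    assert not recs2[0].rsrz_dot


def test_dot_count_equals_outlier_fits(rng):
    n = 40
    recs = [_rec(i) for i in range(n)]
    fits = {}
    for i in range(n):
        z = float(rng.normal(1.0, 1.0))
        fits[("A", i, "")] = ResidueFit(rsr=0.2, rsrz=z, outlier=z > 2.0)
    attach_rsrz_dots(recs, fits)
    assert sum(r.rsrz_dot for r in recs) == sum(f.outlier for f in fits.values())


# ---------------------------------------------------------------------------
# XML + summary

def _full_report(tmp_path):
    bundle = default_bundle()
    stats, _ = make_synthetic_archive(100, seed=9)
    bundle.archive = stats
    entry = make_xray_entry(10, n_unmodeled_tail=2)
    calc = synthesize_map(entry, 0.6)
    obs = make_obs_map(calc, noise_sd=0.03, seed=4)
    return validate_entry(entry, bundle, map_obs=obs, map_calc=calc,
                          stage="preliminary")


def test_xml_validates_and_round_trips(tmp_path):
    report = _full_report(tmp_path)
    path = tmp_path / "report.xml"
    write_xml(report, str(path))          # write_xml validates against the XSD
    back = read_xml(str(path))
    assert back == report                 # lossless round trip


def test_minimal_report_validates(tmp_path):
    report = ValidationReport(entry_id="mini", method="xray",
                              residues=[_rec(1)], metrics={"clashscore": 0.0})
    write_xml(report, str(tmp_path / "mini.xml"))
    assert read_xml(str(tmp_path / "mini.xml")) == report


def test_xml_outlier_counts_match_geometry_module(tmp_path):
    bundle = default_bundle()
    s, truth = inject_distortions(make_helix_peptide(20),
                                  DistortionSpec(bond=2, rama=1, rotamer=1,
                                                 clash=1, seed=8), bundle=bundle)
    report = validate_entry(s, bundle)
    write_xml(report, str(tmp_path / "d.xml"))
    back = read_xml(str(tmp_path / "d.xml"))
    geo = validate_geometry(s, bundle)
    for crit in CRITERIA:
        in_xml = sum(1 for r in back.residues if crit in r.outlier_types)
        in_geo = sum(1 for summ in geo.values()
                     if summ.counts[crit] > 0 and summ.name != "HOH")
        assert in_xml == in_geo


def test_summary_caps_outliers_at_five():
    recs = [ResidueReportRecord("A", i, "SER",
                                outlier_types=frozenset({"clash"})) for i in range(12)]
    recs += [ResidueReportRecord("A", 100 + i, "SER",
                                 outlier_types=frozenset({"bond-length"})) for i in range(3)]
    report = ValidationReport(entry_id="x", method="xray", residues=recs)
    text = write_summary(report)
    assert "Clashing residues: 12" in text
    assert "... and 7 more" in text
    assert "Bond-length outliers: 3" in text
    assert "and 2 more" not in text  # three outliers are all listed


@pytest.mark.parametrize("stage,watermark", [("preliminary", "Preliminary"),
                                             ("confidential", "Confidential"),
                                             ("public", "Public")])
def test_summary_stage_watermark(stage, watermark):
    report = ValidationReport(entry_id="x", method="xray", stage=stage,
                              residues=[_rec(1)])
    assert watermark in write_summary(report)


def test_every_sample_residue_has_one_record():
    entry = make_xray_entry(10, n_unmodeled_tail=3)
    report = validate_entry(entry, default_bundle())
    keys = [(r.chain, r.seq_num) for r in report.residues]
    assert len(keys) == len(set(keys)) == len(entry.sample_sequence["A"])
    assert sum(1 for r in report.residues if not r.modeled) == 3


def test_well_defined_mask_drives_cyan():
    entry = make_xray_entry(10, with_ligand=False)
    mask = {r.key: r.seq_num not in (4, 5) for r in entry.residues()}
    report = validate_entry(entry, default_bundle(), well_defined=mask)
    cyan = {r.seq_num for r in report.residues if r.color == "cyan"}
    assert cyan == {4, 5}
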