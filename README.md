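# strucval

Validation of macromolecular structure models, in the style of the reports
that accompany every PDB deposition. Given an atomic model (PDB or mmCIF) —
and optionally a density map, a reflection list, or chemical-shift lists —
`strucval` computes the standard battery of quality metrics, ranks the entry
against an archive of reference structures, and emits a machine-readable XML
report plus a plain-text summary. It is aimed at structural biologists and
methods developers who want the validation arithmetic as an importable,
testable Python library with fully synthetic, ground-truth fixtures.

## What it computes

**Knowledge-based model checks** (coordinates only):

- Covalent geometry against a restraint dictionary: for each bond/angle,
  *Z* = (obs − target)/σ, flagged at |*Z*| > 4; RMSZ = √(mean *Z*²).
- Ramachandran classification (favored / allowed / outlier) by
  highest-density-region contours on per-class (φ, ψ) reference grids; the
  outlier contour encloses 99.5% of the reference mass, so an outlier sits
  among the rarest 0.5% of conformations.
- Side-chain rotamer classification by circular *Z* distance to canonical
  rotamer modes (outlier when no rotamer is within 3σ per χ).
- Clashscore: non-bonded heavy-atom pairs with van der Waals overlap
  ≥ 0.4 Å, per 1,000 atoms, including contacts to crystallographic symmetry
  images.
- cis/twisted peptides (|ω| < 30° / 30–150°), Cα chirality by signed
  tetrahedral volume, and ligand geometry against fragment statistics
  (bond and angle RMSZ).

**Fit to experimental data:**

- Per-residue real-space R, RSR = Σ|ρ_obs − ρ_calc| / Σ(|ρ_obs| + |ρ_calc|)
  over a mask around the residue, normalized by residue type and resolution
  band to RSRZ; residues with RSRZ > 2 are outliers.
- LLDF for ligands: a local *Z* score of the ligand's RSR against the
  mean/SD of RSRs of standard residues within 5.0 Å (symmetry included);
  undefined with fewer than two neighbors; values > 2 are highlighted.
- R and R_free from a reflection list, with the linear scale fit on the
  working set only.

**Archive context:** every key metric gets two percentile ranks — absolute
(whole archive) and relative (entries of similar resolution, window widened
until ≥ 1,000 entries; NMR/EM entries are ranked among their own method).
Archive statistics are rebuilt from per-entry records with
`build_archive_stats`, the same path used for annual recalculation.

**Reports:** per-residue color coding (green / yellow / orange / red for
0 / 1 / 2 / ≥3 distinct outlier criteria, gray for residues present in the
sample but not in the model, cyan for ensemble-ill-defined residues, a red
dot for RSRZ > 2), chain-quality fractions, XML validated against the
packaged XSD, and a text summary listing at most five outliers per metric.

A first-class synthetic-fixture module (`strucval.synth`) generates every
input with known ground truth: ideal helical peptides built from the same
restraint dictionary the validator uses, structures with exactly planted
defects, toy ligands at fragment-statistics means, noisy observed maps with
deliberately erased density, synthetic archives, and shift lists.

## Worked example

```python
from strucval.geometry import entry_geometry_metrics, validate_geometry
from strucval.refdata import default_bundle
from strucval.synth import DistortionSpec, inject_distortions, make_helix_peptide

bundle = default_bundle()
spec = DistortionSpec(bond=1, angle=1, rama=1, rotamer=1, clash=1,
                      chirality=1, seed=42)
structure, truth = inject_distortions(make_helix_peptide(25), spec, bundle=bundle)
result = validate_geometry(structure, bundle)
for summ in result.values():
    if summ.outlier_types:
        print(summ.residue, sorted(summ.outlier_types))
print(entry_geometry_metrics(result, structure))
```

prints (see `examples/geometry_checks.py` for the full script):

```
('A', 12, '') ['bond-angle']
('A', 14, '') ['clash']
('A', 18, '') ['rotamer-or-torsion']
('A', 19, '') ['bond-length']
('A', 23, '') ['chirality']
('A', 24, '') ['ramachandran']
('A', 9000, '') ['clash']
{'clashscore': 26.49..., 'rama_outlier_pct': 4.347..., 'rotamer_outlier_pct': 4.0}
```

Each planted defect is recovered at exactly the planted residue and nowhere
else (residue 9000 is the water partner of the planted clash); the entry
metrics are the per-1,000-atom clash rate and the percentage of assessable
residues flagged by each torsion criterion.

Other narrative scripts in `examples/` cover the density-fit measures and
LLDF (`density_fit.py`), percentile sliders (`percentile_sliders.py`),
chemical-shift validation (`chemical_shifts.py`) and the end-to-end XML
report (`full_report.py`). The same functionality is scriptable from the
shell:

```
strucval synth entry --n-res 20 --bond 1 --clash 1 --seed 4 --out bad.pdb
strucval validate bad.pdb --out report.xml --summary report.txt
```

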