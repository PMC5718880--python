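# Methods

This note documents the models and conventions behind `strucval`: what each
validator computes, the tunable parameters and their defaults, what the
synthetic fixtures emulate (and deliberately do not), and the choices made
where the design was genuinely open.

## Structure model and coordinate handling

Coordinates are Cartesian Ångströms throughout; fractional coordinates are
used only inside the symmetry machinery. Author residue numbering is kept as
read; no renumbering. Where an atom has alternate locations, every check
uses the highest-occupancy conformer (ties broken by alphabetical alt-loc
id), giving a single deterministic model per check. Hydrogens are parsed but
excluded from clash detection and density masks by default (a flag restores
them); the synthetic fixtures are heavy-atom only. Parsing and writing of
PDB/mmCIF and CCP4 maps is delegated to gemmi; only the subset the pipeline
needs is interpreted (coordinates, cell, symmetry, resolution, method,
entity sequence). A model without a unit cell gets a P1 bounding box with a
10 Å margin and has its symmetry-dependent checks disabled.

Backbone torsions follow the IUPAC sign convention; ω(i) is the torsion of
the peptide bond linking residue i−1 to residue i. Angles with missing atoms
are undefined, not errors, and degenerate (collinear) quadruples return
undefined.

Symmetry images are generated by applying every symmetry operator plus the
3×3×3 block of lattice translations to the cell-wrapped asymmetric unit and
keeping images within the query radius of any model atom. This covers any
radius smaller than the shortest cell edge, which is ample for contact
radii. The implementation uses a k-d tree but is tested to agree exactly
with the brute-force 27-translate enumeration.

## Reference bundle

All references live in one `ReferenceBundle`: covalent geometry targets,
Ramachandran grids, a rotamer library, small-molecule fragment statistics,
archive metric distributions, chemical-shift statistics, plus van der Waals
and covalent radii, chirality expectations and expected-atom tables. The
validation engine is agnostic to a bundle's provenance; bundles serialize to
a directory of JSON files that are structurally validated on load (positive
sigmas, complete backbone coverage, normalized grids). The packaged default
is generated programmatically from documented analytic families rather than
shipped as static data, which keeps the package text-only and — more
importantly — lets the fixture generator build "ideal" structures from the
*same* numbers the validator checks against, eliminating reference mismatch
in tests.

- **Covalent targets** are Engh–Huber-style restraint values for the
  backbone (N–CA 1.459(20) Å, CA–C 1.525(26) Å, C–O 1.229(19) Å, N–CA–C
  111.0(2.8)°, CA–C–O 120.1(2.1)°, …), CB geometry, peptide-link entries
  (C–N 1.336(23) Å, CA–C–N 117.2(2.2)°, C–N–CA 121.7(2.5)°) and a few
  serine/cysteine/threonine side-chain entries.
- **Ramachandran grids** (classes general, GLY, PRO, pre-PRO) are mixtures
  of periodic 2-D Gaussians centred on the helical, sheet and left-helical
  basins, on 4° bins. Classification uses highest-density-region contours:
  a conformation is *favored* when the cumulative mass of all bins at least
  as dense is ≤ 0.95, an *outlier* beyond 0.995 — the "rarest 0.5%"
  convention. The favored level is a bundle parameter (the published
  favored/allowed boundary is not prescribed anywhere; 95% is the common
  choice).
- **Rotamers** are canonical m/p/t χ₁ modes (σ = 12°) with coarse χ₂⁺
  extensions; frequencies are priors only — classification uses the max
  over χ of circular distance/σ, nearest rotamer wins, ties break by
  library order, outlier when the best score exceeds 3.
- **Fragment statistics** for ligands are keyed by canonicalized
  (element, heavy-atom connectivity count) descriptors — bond keys are
  sorted pairs, angle keys center-plus-sorted-outer triples. This is a
  deterministic, chemistry-aware scheme computable without access to any
  external small-molecule corpus; the shipped numbers are survey-style
  means/sds for common C/N/O fragments.
- **Chemical-shift statistics** are mean/sd per (residue, atom, nucleus)
  with a wildcard-residue fallback.

## Geometry validation

Covalent deviations are plain Z scores; |Z| > 4 flags an outlier (a common
crystallographic convention; configurable). Ligand fragment comparison flags
|Z| > 2 and reports bond and angle RMSZ separately, counting unmatched
fragments rather than scoring them.

Clash detection uses a vdW-overlap criterion: two non-bonded heavy atoms
clash when r₁ + r₂ − d ≥ 0.4 Å. Connectivity is inferred from covalent
radii (sum + 0.4 Å tolerance) within residues plus explicit peptide links;
excluded pairs are bonded (1-2), angle (1-3) and torsion (1-4) pairs and
disulfide-bonded sulfur pairs. The 1-4 exclusion is deliberate: under a pure
overlap criterion the ideal trans peptide's O(i)–CA(i+1) separation
(~2.78 Å) would otherwise flag every peptide bond, and 1-4 separations are
set by torsions, not by non-bonded contacts. Probe-style dot scoring with
explicit hydrogens is richer; this criterion is the package's documented
stand-in. Symmetry contacts are included and deduplicated by canonical pair
key (a clash of a with an image of b is the same contact as b with the
inverse image of a). The spatial index is tested to be exactly equivalent to
an all-pairs scan.

Chirality is checked as the sign of the tetrahedral volume
det[N−CA, C−CA, CB−CA] at each α-carbon (positive = L). cis/twisted peptide
cuts are |ω| < 30° and 30° ≤ |ω| ≤ 150° — documented conventions.

## Density fit

The model map is an analytic sum of normalized isotropic Gaussians, one per
atom: amplitude Z·occupancy, width σ² = B/(8π²) (B floored at 5 Å² to keep
widths sane), evaluated with periodic wrapping; the integral of an isolated
atom equals Z·occupancy, which provides a closed-form oracle. Observed maps
come from CCP4 files or from the fixture path (model map + seeded white
noise, optionally with residue density erased to background); computing
likelihood-weighted maps from experimental amplitudes is out of scope.

RSR masks are all grid points within 1.8 Å of any heavy atom of the residue
(resolution-independent default). RSRZ = (RSR − μ)/σ with μ, σ from the
archive per (residue type, resolution band); the band edges
[0, 1.0, 1.4, 1.8, 2.2, 2.6, 3.0, ∞) Å are stored in the bundle as data.
Flagging is one-sided (RSRZ > 2): an unusually *good* local fit is not an
outlier. Residues whose type/band has no reference statistics have undefined
RSRZ and are excluded from both numerator and denominator of the
RSRZ-outlier percentage.

LLDF uses the sample (n−1) standard deviation of the neighbors' RSRs; with
fewer than two neighbors within 5.0 Å (or a zero-SD neighborhood) it is
undefined, and values > 2 are highlighted — both one-sided by definition.
Neighbor identification uses heavy atoms only, consistent with the hydrogen
policy, and includes crystallographic symmetry images. A practical caveat
the fixtures expose: with only two or three neighbors the SD estimate is
noisy, so LLDF can exceed 2 for unremarkable ligands; the neighbor count is
always reported alongside.

R factors: R = Σ| |F_obs| − k·|F_calc| | / Σ|F_obs| per subset, with the
scale k = ΣF_obs·F_calc / ΣF_calc² fit on the working set only, so R_free is
evaluated with a scale it did not influence.

## Percentiles and sliders

Percentile = 100·(n_worse + 0.5·n_equal)/n_total (midrank tie handling; tie
convention is ours, stated here because no published one exists). All five
slider metrics are lower-is-better, so "worse" means larger. Relative ranks
for crystal entries use a symmetric resolution window grown from ±0.1 Å in
±0.1 Å steps until it holds min(1000, n_archive) entries — a deterministic
schedule stored in configuration; NMR/EM entries are ranked within their own
method's pool. Percentiles are kept at full precision internally and rounded
only for presentation.

## Reports

The residue color model counts *distinct* outlier criteria among
{bond length, bond angle, Ramachandran, rotamer/torsion, clash, chirality}:
0 → green, 1 → yellow, 2 → orange, ≥3 → red; unmodeled sample residues are
gray and ensemble-ill-defined residues cyan. Bond length and bond angle
count as two separate criteria. Density fit is a separate red-dot channel
and never enters the color count. Chain stacked-bar fractions use the
sample-sequence length as denominator, so gray is the unmodeled fraction.
The well-defined mask defaults to all-true; users may supply one computed
elsewhere (ensemble-core identification is not reimplemented here).

XML reports validate against the packaged XSD on every write; floats are
serialized with `repr` so read(write(r)) == r exactly. The text summary
lists at most five outliers per metric with an "… and N more" remainder and
carries the report-stage watermark (Preliminary / Confidential / Public).
PDF rendering is out of scope.

## Synthetic fixtures

`make_helix_peptide` builds poly-serine α-helices by internal-coordinate
(NeRF) construction directly from the bundle's restraint targets, with
(φ, ψ) = (−57, −47), trans peptides, and CB placed by solving the improper
torsion so both flanking angles hit their targets in the L configuration —
so every covalent Z is numerically zero and the clean fixture is clean by
construction. Serine is the default residue because it is the smallest
rotamer-bearing side chain.

`inject_distortions` plants defects on disjoint residues with exact truth
labels: bonds stretch the terminal carbonyl O along its axis (+6σ, so
Z = 6 exactly); angles rotate O in the CA–C–O plane (choosing the rotation
sense that stays clear of neighboring atoms); backbone-torsion outliers
drive (φ, ψ) to (−80, 60) via pure bond rotations at chain-terminal
positions (three residues apart) so the swung segment stays short; rotamer
defects rotate χ₁ to 120° (≥4.5σ from every mode); chirality defects
reflect the side chain through the N–CA–C plane (an isometry, so only the
stereocenter flips); clashes add a water oxygen 2.2 Å from a carbonyl O
along the clearest direction on a cone around the C=O axis. Because planted
defects must not interact (a swung tail grazing a planted water would
entangle two truth labels), the generator verifies the planted configuration
against the validators and redraws the residue assignment — seeded and
deterministic — when an interaction occurs. Detection sensitivity is not
assumed: if a validator failed to flag its planted defect the generator
would exhaust its retries and raise.

`make_synthetic_archive` draws entries with resolutions uniform on
1.0–3.5 Å and metric values from documented resolution-dependent families
(normal for R_free and outlier percentages, clipped to physical ranges;
lognormal for clashscore); per-residue RSR draws are normal with a
band-dependent mean (0.10 + 0.02·band) and SD 0.03. These are desk-scale
stand-ins chosen to span realistic ranges, not fits to any survey; passing
tests therefore demonstrate correctness of the *arithmetic* (normalization,
ranking, recovery), not agreement with archive-wide empirical statistics.
Real structures also differ from the fixtures in ways that matter for
absolute numbers: real maps have correlated, resolution-dependent noise (not
white), real side chains pack sequence-dependently, and real reference
dictionaries are larger.

Problem sizes used by the test suite and the acceptance script (helices of
10–25 residues, archives of a few hundred to ~1,200 entries, maps at
0.5–0.8 Å spacing, 40–100 seeded fixture replicates) were chosen so the
whole battery runs comfortably on a laptop; every size is a parameter.

## Numerical conventions

Dihedrals return (−180°, 180°] and are undefined for collinear quadruples
(tolerance 10⁻⁹ on the normal cross products). Circular distances are taken
modulo 360°. Nearest-rotamer ties break by library order; archive records
sort by (value, resolution, method) so serialization is byte-stable under
input permutation. RSR returns undefined (not 0) for empty masks or
all-zero denominators; clashscore is undefined at zero atoms; every
undefined value propagates as "n/a" rather than a sentinel number.

## Known limitations

No hydrogen placement or contact-dot scoring; no RNA backbone conformer
scoring; no re-refinement or experimental-data pathology checks; no
map-coefficient calculation from amplitudes; no automatic ensemble
well-defined-core detection; shift input is a documented CSV rather than
NMR-STAR; the non-severe shift-outlier threshold (|Z| > 5) and the covalent
|Z| > 4 cut are package defaults, stated here because no published value
pins them down.
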