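"""Density fit: map synthesis, RSR, RSRZ normalization, LLDF, R factors."""

import math

import numpy as np
import pytest

import gemmi
from strucval.density import (
    DensityMap,
    ReflectionSet,
    find_ligand_neighbors,
    lldf,
    mask_indices,
    r_factors,
    read_ccp4_map,
    residue_fits,
    residue_rsr,
    rsrz,
    synthesize_map,
    write_ccp4_map,
)
from strucval.model import Atom, Method, Residue, StructureModel, UnitCell
from strucval.refdata import build_archive_stats
from strucval.synth import (
    make_obs_map,
    make_synthetic_archive,
    make_toy_ligand,
    make_xray_entry,
)


def _single_atom_structure(pos=(7.5, 7.5, 7.5), element="C", b_iso=20.0):
    atom = Atom("X", element, np.array(pos, dtype=float), 1.0, b_iso)
    return StructureModel(models=[{"A": [Residue("A", 1, "LIG", [atom])]}],
                          cell=UnitCell(15, 15, 15), method=Method.XRAY)


def test_map_integral_matches_closed_form():
    """A single Gaussian atom integrates to Z x occupancy."""
    s = _single_atom_structure()
    m = synthesize_map(s, spacing=0.3)
    voxel = (15.0 / m.shape[0]) * (15.0 / m.shape[1]) * (15.0 / m.shape[2])
    z_carbon = gemmi.Element("C").atomic_number
    assert m.values.sum() * voxel == pytest.approx(z_carbon, rel=0.01)


def test_map_translation_by_one_grid_step_shifts_indices():
    spacing = 15.0 / 30
    s1 = _single_atom_structure((7.5, 7.5, 7.5))
    s2 = _single_atom_structure((7.5 + spacing, 7.5, 7.5))
    m1 = synthesize_map(s1, spacing=spacing)
    m2 = synthesize_map(s2, spacing=spacing)
    assert np.allclose(np.roll(m1.values, 1, axis=0), m2.values, atol=1e-12)


def test_map_linearity():
    s1 = _single_atom_structure((5.0, 7.5, 7.5))
    s2 = _single_atom_structure((10.0, 7.5, 7.5))
    both = _single_atom_structure((5.0, 7.5, 7.5))
    both.models[0]["A"].append(Residue("A", 2, "LIG",
                                       [Atom("Y", "C", np.array([10.0, 7.5, 7.5]))]))
    m1 = synthesize_map(s1, 0.5)
    m2 = synthesize_map(s2, 0.5)
    mb = synthesize_map(both, 0.5)
    assert np.abs(mb.values - (m1.values + m2.values)).max() < 1e-12


def test_empty_structure_rejected():
    s = _single_atom_structure()
    s.models[0]["A"][0].atoms.clear()
    with pytest.raises(ValueError):
        synthesize_map(s)


def test_ccp4_round_trip(tmp_path):
    s = _single_atom_structure()
    m = synthesize_map(s, 0.5)
    p = tmp_path / "m.ccp4"
    write_ccp4_map(m, str(p))
    back = read_ccp4_map(str(p))
    assert back.shape == m.shape
    assert np.abs(back.values - m.values).max() < 1e-5
    assert back.cell.a == pytest.approx(15.0, abs=1e-4)


def test_rsr_limits(xray_entry):
    m = synthesize_map(xray_entry, 0.5)
    lig = xray_entry.chains["L"][0]
    assert residue_rsr(lig, m, m) == 0.0                 # identical maps
    neg = m.copy()
    neg.values = -neg.values
    assert residue_rsr(lig, neg, m) == 1.0               # sign-flipped maps


def test_rsr_matches_explicit_mask_oracle(xray_entry, rng):
    m = synthesize_map(xray_entry, 0.6)
    obs = m.copy()
    obs.values = obs.values + rng.normal(0, 0.05, obs.values.shape)
    res = xray_entry.chains["A"][5]
    mask = mask_indices(res.heavy_coords(), m, 1.8)
    a, b = obs.values[mask], m.values[mask]
    expected = np.abs(a - b).sum() / (np.abs(a).sum() + np.abs(b).sum())
    assert residue_rsr(res, obs, m) == pytest.approx(float(expected), rel=1e-12)


def test_rsr_bounded_by_one_for_nonnegative_maps(xray_entry, rng):
    m = synthesize_map(xray_entry, 0.6)
    obs = m.copy()
    obs.values = np.abs(obs.values + rng.normal(0, 0.1, obs.values.shape))
    for res in xray_entry.residues():
        r = residue_rsr(res, obs, m)
        if r is not None:
            assert 0.0 <= r <= 1.0


def test_noise_monotonicity_of_median_rsr(xray_entry):
    """More observed-map noise never lowers the median residue RSR."""
    m = synthesize_map(xray_entry, 0.6)
    medians = []
    for sd in (0.0, 0.05, 0.15):
        reps = []
        for seed in range(20):
            obs = make_obs_map(m, noise_sd=sd, seed=seed)
            fits = residue_fits(xray_entry, obs, m)
            reps.append(np.median([f.rsr for f in fits.values() if f.rsr is not None]))
        medians.append(np.median(reps))
    assert medians[0] <= medians[1] <= medians[2]


# ---------------------------------------------------------------------------
# RSRZ

def _norm_stats():
    obs = [("SER", 2.0, v) for v in (0.10, 0.12, 0.14, 0.16, 0.18)]
    return build_archive_stats([{"clashscore": 1.0, "resolution": 2.0, "method": "xray"}],
                               snapshot_date="d", rsr_observations=obs)


def test_rsrz_formula_and_one_sided_rule():
    stats = _norm_stats()
    mean, sd = stats.rsr_band("SER", 2.0)
    z, flag = rsrz(mean, "SER", 2.0, stats)
    assert z == pytest.approx(0.0, abs=1e-12) and not flag
    z, flag = rsrz(mean + 2.5 * sd, "SER", 2.0, stats)
    assert z == pytest.approx(2.5, abs=1e-9) and flag
    z, flag = rsrz(mean - 3.0 * sd, "SER", 2.0, stats)
    assert not flag  # one-sided: very good fit is not an outlier


def test_rsrz_missing_band_undefined():
    stats = _norm_stats()
    assert rsrz(0.2, "TRP", 2.0, stats) == (None, False)


def test_rsrz_self_normalization():
    """Archive built from a calibration set standardizes that same set."""
    stats, truth = make_synthetic_archive(300, seed=21)
    per_band = {}
    for rt, res, v in truth["rsr_observations"]:
        z, _ = rsrz(v, rt, res, stats)
        if z is not None:
            per_band.setdefault(stats.band_index(res), []).append(z)
    for band, zs in per_band.items():
        a = np.asarray(zs)
        if a.size >= 200:
            assert abs(a.mean()) < 0.1
            assert abs(a.std(ddof=1) - 1.0) < 0.1


# ---------------------------------------------------------------------------
# LLDF

def test_lldf_requires_two_neighbors(xray_entry):
    lig = xray_entry.chains["L"][0]
    fit = lldf(lig, {}, xray_entry)   # empty RSR table -> zero usable neighbors
    assert fit.lldf is None and fit.n_neighbors < 2
    assert fit.reason == "fewer than two neighbors"


def test_lldf_hand_computed_value(xray_entry):
    lig = xray_entry.chains["L"][0]
    neighbors = find_ligand_neighbors(lig, xray_entry)
    assert len(neighbors) >= 2
    table = {k: v for k, v in zip(neighbors, (0.10, 0.14, 0.18))}
    fit = lldf(lig, table, xray_entry, ligand_rsr=0.26)
    # neighbors mean 0.14, sample sd 0.04 -> (0.26 - 0.14) / 0.04 = 3.0
    assert len(neighbors) == 3
    assert fit.lldf == pytest.approx(3.0, abs=1e-9)
    assert fit.highlighted


def test_lldf_degenerate_neighborhood(xray_entry):
    lig = xray_entry.chains["L"][0]
    neighbors = find_ligand_neighbors(lig, xray_entry)
    table = {k: 0.15 for k in neighbors}
    fit = lldf(lig, table, xray_entry, ligand_rsr=0.3)
    assert fit.lldf is None and fit.reason == "degenerate neighborhood"


def test_lldf_affine_invariance(xray_entry):
    lig = xray_entry.chains["L"][0]
    neighbors = find_ligand_neighbors(lig, xray_entry)
    table = {k: v for k, v in zip(neighbors, (0.08, 0.13, 0.21))}
    base = lldf(lig, table, xray_entry, ligand_rsr=0.3).lldf
    alpha, beta = 2.5, 0.07
    scaled = {k: alpha * v + beta for k, v in table.items()}
    again = lldf(lig, scaled, xray_entry, ligand_rsr=alpha * 0.3 + beta).lldf
    assert again == pytest.approx(base, rel=1e-9)


def _brute_force_neighbors(lig, structure, radius=5.0):
    from strucval.model import ResidueKind, symmetry_images
    lig_xyz = lig.heavy_coords()
    found = set()
    for res in structure.residues():
        if res.key == lig.key or res.kind not in (ResidueKind.STANDARD_AA,
                                                  ResidueKind.STANDARD_NT):
            continue
        xyz = res.heavy_coords()
        d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= radius:
            found.add(res.key)
    for res, _a, img, _op, _s in symmetry_images(structure, radius):
        if res.kind not in (ResidueKind.STANDARD_AA, ResidueKind.STANDARD_NT):
            continue
        if np.linalg.norm(lig_xyz - img.pos, axis=1).min() <= radius:
            found.add(res.key)
    return found


@pytest.mark.parametrize("seed", range(10))
def test_lldf_neighbors_match_brute_force(seed):
    """Random ligand placements (some near the periodic boundary): neighbor
    set equals the all-pairs 5 A search including symmetry images."""
    rng = np.random.default_rng(seed)
    entry = make_xray_entry(10, with_ligand=False)
    entry.cell = UnitCell(28, 28, 28)
    lig, _ = make_toy_ligand(center=rng.uniform(0, 28, 3))
    entry.models[0]["L"] = [lig]
    got = set(find_ligand_neighbors(lig, entry))
    assert got == _brute_force_neighbors(lig, entry)


# ---------------------------------------------------------------------------
# R factors

def test_r_factors_identity_and_scale_invariance(rng):
    n = 200
    fc = np.abs(rng.normal(50, 15, n))
    free = rng.random(n) < 0.08
    hkl = dict(h=np.arange(n), k=np.zeros(n, int), l=np.zeros(n, int))
    same = ReflectionSet(**hkl, f_obs=fc.copy(), f_calc=fc, free=free)
    assert r_factors(same) == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))
    doubled = ReflectionSet(**hkl, f_obs=2.0 * fc, f_calc=fc, free=free)
    assert r_factors(doubled) == (pytest.approx(0.0, abs=1e-12), pytest.approx(0.0, abs=1e-12))


def test_r_factors_match_oracle(rng):
    n = 300
    fc = np.abs(rng.normal(40, 10, n))
    fo = np.abs(1.3 * fc + rng.normal(0, 5, n))
    free = rng.random(n) < 0.1
    rs = ReflectionSet(np.arange(n), np.zeros(n, int), np.zeros(n, int), fo, fc, free)
    r_work, r_free = r_factors(rs)
    w = ~free
    k = (fo[w] * fc[w]).sum() / (fc[w] ** 2).sum()
    assert r_work == pytest.approx(np.abs(fo[w] - k * fc[w]).sum() / fo[w].sum(), rel=1e-12)
    assert r_free == pytest.approx(np.abs(fo[free] - k * fc[free]).sum() / fo[free].sum(), rel=1e-12)


def test_r_factors_empty_subset():
    n = 10
    fc = np.ones(n)
    rs = ReflectionSet(np.arange(n), np.zeros(n, int), np.zeros(n, int),
                       fc, fc, np.zeros(n, bool))
    r_work, r_free = r_factors(rs)
    assert r_work == 0.0 and r_free is None
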