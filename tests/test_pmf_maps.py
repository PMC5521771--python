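"""Map loading, synthesis, feature extraction and restricted sampling."""

import numpy as np
import pytest
from scipy import stats

import chitosim as cs
from chitosim.pmf_maps import (
    MAP_FEATURE_TABLE,
    MapFormatError,
    MapLibraryError,
    _angdiff,
    load_map,
    write_map,
)

TWO_PI = 2 * np.pi


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_uniform_grid_normalizes_to_zero(tmp_path):
    path = tmp_path / "flat.dat"
    n = 20
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(n):
                fh.write(f"{(i+0.5)*TWO_PI/n} {(j+0.5)*TWO_PI/n} 3.0\n")
    m = load_map(path, grid_spec=50)
    assert m.grid.min() == 0.0
    assert np.allclose(m.grid, 0.0)
    assert m.offset == pytest.approx(3.0)


def test_single_deep_bin_normalization(tmp_path):
    path = tmp_path / "deep.dat"
    n = 40
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(n):
                g = -5.0 if (i, j) == (7, 9) else 0.0
                fh.write(f"{(i+0.5)*TWO_PI/n},{(j+0.5)*TWO_PI/n},{g}\n")
    m = load_map(path, grid_spec=n)
    assert m.grid.min() == 0.0
    assert m.grid[7, 9] == 0.0
    mask = np.ones((n, n), bool)
    mask[7, 9] = False
    assert np.allclose(m.grid[mask], 5.0)


def test_dense_matrix_dialect_and_kjmol(tmp_path):
    path = tmp_path / "dense.dat"
    n = 10
    rows = np.arange(n * n, dtype=float).reshape(n, n)
    with open(path, "w") as fh:
        fh.write(f"# phi 0 {TWO_PI} psi 0 {TWO_PI} kJ/mol\n")
        for r in rows:
            fh.write(" ".join(f"{v}" for v in r) + "\n")
    m = load_map(path, grid_spec=n)
    # energies divided by k_B T in kJ/mol; min removed
    assert m.grid.max() == pytest.approx((n * n - 1) / cs.pmf_maps.KBT_KJMOL_298)


def test_negative_angle_convention_shifted(tmp_path):
    """A [-pi, pi) file lands on the same map as its [0, 2pi) twin."""
    n = 16
    well = cs.synthesize_map([cs.Well(4.0, 2.0, 6.0, 0.5, 0.5)], 6.0, grid_spec=n)
    p1, p2 = tmp_path / "a.dat", tmp_path / "b.dat"
    phi_c, psi_c = well.bin_centers()
    with open(p1, "w") as fh, open(p2, "w") as fh2:
        for i, p in enumerate(phi_c):
            for j, q in enumerate(psi_c):
                fh.write(f"{p} {q} {well.grid[i, j]}\n")
                ps = p if p < np.pi else p - TWO_PI
                qs = q if q < np.pi else q - TWO_PI
                fh2.write(f"{ps} {qs} {well.grid[i, j]}\n")
    m1 = load_map(p1, grid_spec=n)
    m2 = load_map(p2, grid_spec=n)
    assert np.allclose(m1.grid, m2.grid, atol=1e-10)


@pytest.mark.parametrize(
    "content,match",
    [
        ("1.0 2.0\n", "header"),
        ("1.0 2.0 zzz\n", "malformed"),
        ("0.1 0.1 1.0\n0.1 0.2 1.0\n0.2 0.1 1.0\n", "rectangular"),
    ],
)
def test_malformed_files_raise(tmp_path, content, match):
    path = tmp_path / "bad.dat"
    path.write_text(content)
    with pytest.raises(MapFormatError, match=match):
        load_map(path)


def test_write_read_round_trip(tmp_path, two_well_map):
    path = tmp_path / "rt.dat"
    write_map(path, two_well_map)
    m = load_map(path, grid_spec=two_well_map.n_phi)
    assert np.allclose(m.grid, two_well_map.grid, atol=1e-6)


# ---------------------------------------------------------------------------
# interpolation / periodicity
# ---------------------------------------------------------------------------

def test_periodic_continuity(two_well_map):
    m = two_well_map
    phis = np.linspace(0, TWO_PI, 17)
    assert np.allclose(m.energy(phis, 1.3), m.energy(phis + TWO_PI, 1.3), atol=1e-12)
    assert np.allclose(m.energy(0.0, phis), m.energy(0.0, phis - TWO_PI), atol=1e-12)
    # seam: value at phi=0 equals value at phi=2pi
    assert m.energy(0.0, 2.0) == pytest.approx(m.energy(TWO_PI, 2.0), abs=1e-12)


def test_scalar_matches_vector_interpolation(two_well_map, rng):
    pts = rng.uniform(0, TWO_PI, (50, 2))
    vec = two_well_map.energy(pts[:, 0], pts[:, 1])
    sca = [two_well_map.energy_scalar(p, q) for p, q in pts]
    assert np.allclose(vec, sca, atol=1e-10)


# ---------------------------------------------------------------------------
# synthesis + features
# ---------------------------------------------------------------------------

def test_single_well_has_one_minimum():
    m = cs.synthesize_map([cs.Well(3.0, 3.0, 8.0, 0.3, 0.3)], 8.0)
    mins = cs.find_minima(m)
    assert len(mins) == 1
    assert cs.delta_g2(m) is None


def test_two_well_gap_recovered(two_well_map):
    """Generator oracle: construction gap 4.0 k_BT within grid resolution."""
    gap = cs.delta_g2(two_well_map)
    assert gap == pytest.approx(4.0, abs=0.05)
    mins = cs.distinct_minima(two_well_map)
    assert len(mins) == 2
    dphi = TWO_PI / two_well_map.n_phi
    assert abs(_angdiff(mins[0][0], 4.997)) < dphi
    assert abs(_angdiff(mins[0][1], 2.188)) < dphi
    assert abs(_angdiff(mins[1][1], 2.188 - np.pi)) < dphi


def test_flat_map_has_no_minima():
    m = cs.DihedralMap(np.zeros((50, 50)))
    with pytest.warns(UserWarning, match="flat"):
        assert cs.find_minima(m) == []


def test_overlapping_wells_warn():
    with pytest.warns(UserWarning, match="merged"):
        cs.synthesize_map(
            [cs.Well(3.0, 3.0, 8.0, 0.4, 0.4), cs.Well(3.1, 3.05, 7.0, 0.4, 0.4)],
            8.0,
        )


def test_area_fraction_equals_direct_count(two_well_map):
    """Brute-force count oracle, independent of the implementation."""
    for thr in (1.0, 7.0, 12.0):
        count = sum(
            1
            for i in range(two_well_map.n_phi)
            for j in range(two_well_map.n_psi)
            if two_well_map.grid[i, j] <= thr
        )
        assert cs.accessible_area_fraction(two_well_map, thr) == pytest.approx(
            count / two_well_map.grid.size
        )
    strict_count = int((two_well_map.grid < 1.0).sum())
    assert cs.accessible_area_fraction(two_well_map, 1.0, strict=True) == (
        strict_count / two_well_map.grid.size
    )


def test_flat_map_area_is_one():
    m = cs.DihedralMap(np.zeros((20, 20)))
    assert cs.accessible_area_fraction(m, 0.5) == 1.0


def test_library_reproduces_published_features(library):
    """The calibrated synthetic maps match the published per-link feature
    table: minimum position, ΔG₂ and both area fractions."""
    for key, (a12, a1, phi0, psi0, dg2) in MAP_FEATURE_TABLE.items():
        m = library.maps[key]
        feats = cs.map_features(m)
        got_phi, got_psi, _ = feats.minima[0]
        assert abs(_angdiff(got_phi, phi0)) < 0.02, key
        assert abs(_angdiff(got_psi, psi0)) < 0.02, key
        assert feats.delta_g2 == pytest.approx(dg2, abs=0.05), key
        assert feats.area_12kt * 100 == pytest.approx(a12, abs=0.3), key
        assert feats.area_1kt * 100 == pytest.approx(a1, abs=0.05), key
        assert feats.area_1kt <= feats.area_12kt


# ---------------------------------------------------------------------------
# restriction & sampling
# ---------------------------------------------------------------------------

def test_restrict_infinite_cutoff_allows_all(two_well_map):
    region = cs.restrict(two_well_map, 1e9)
    assert region.bin_count == two_well_map.grid.size


def test_restrict_small_cutoff_is_minimum_neighborhood(two_well_map):
    region = cs.restrict(two_well_map, 0.05)
    assert 0 < region.bin_count < 30


def test_restricted_sampler_uniform_and_contained(rng):
    """Sampler occupancy is uniform over allowed bins (chi-square) and no
    sample falls outside; interpolated energies stay near the cutoff."""
    m = cs.synthesize_map([cs.Well(3.0, 3.0, 9.0, 0.8, 0.8)], 9.0, grid_spec=50)
    region = cs.restrict(m, 4.0)
    n_samp = 200_000
    phi, psi = region.sample(rng, size=n_samp)
    i = (phi / TWO_PI * 50).astype(int)
    j = (psi / TWO_PI * 50).astype(int)
    flat = i * 50 + j
    allowed = set(region.allowed_flat.tolist())
    assert set(np.unique(flat)) <= allowed
    counts = np.bincount(
        np.searchsorted(region.allowed_flat, flat), minlength=region.bin_count
    )
    p = stats.chisquare(counts).pvalue
    assert p > 0.01
    # smooth map: interpolated energy within half a bin's variation of cutoff
    e = m.energy(phi[:5000], psi[:5000])
    grad_bound = np.abs(np.diff(m.grid, axis=0)).max() + np.abs(
        np.diff(m.grid, axis=1)
    ).max()
    assert e.max() <= 4.0 + grad_bound


def test_restrict_rejects_bad_cutoff(two_well_map):
    with pytest.raises(ValueError):
        cs.restrict(two_well_map, -1.0)


# ---------------------------------------------------------------------------
# library lookups
# ---------------------------------------------------------------------------

def test_map_for_link_lookup(library):
    m = library.map_for_link(cs.GLCNH3, cs.GLCNAC)
    assert m.link_key == (cs.GLCNH3, cs.GLCNAC)
    with pytest.raises(MapLibraryError, match="unknown monomer state"):
        library.map_for_link("GlcX", cs.GLCNAC)


def test_protonation_changes_lookup_key():
    seq = cs.build_sequence(3, 1.0, "AAA"[:3])
    assert seq.link_key(0) == (cs.GLCNH2, cs.GLCNH2)
    seq.charges[0] = 1
    assert seq.link_key(0) == (cs.GLCNH3, cs.GLCNH2)
    assert seq.link_key(1) == (cs.GLCNH2, cs.GLCNH2)


def test_missing_key_raises():
    lib = cs.MapLibrary(
        maps={(cs.GLCNAC, cs.GLCNAC): cs.DihedralMap(np.zeros((10, 10)))}
    )
    with pytest.raises(MapLibraryError, match="missing"):
        lib.map_for_link(cs.GLCNH2, cs.GLCNH2)
    with pytest.raises(MapLibraryError):
        lib.validate_complete()


def test_inconsistent_grid_shapes_rejected():
    with pytest.raises(MapFormatError, match="inconsistent"):
        cs.MapLibrary(
            maps={
                (cs.GLCNAC, cs.GLCNAC): cs.DihedralMap(np.zeros((10, 10))),
                (cs.GLCNAC, cs.GLCNH2): cs.DihedralMap(np.zeros((20, 20))),
            }
        )


def test_manifest_round_trip(tmp_path, two_well_map):
    write_map(tmp_path / "m.dat", two_well_map)
    lines = []
    for a in cs.MONOMER_STATES:
        for b in cs.MONOMER_STATES:
            lines.append(f"{a} {b} m.dat")
    (tmp_path / "manifest.txt").write_text("\n".join(lines) + "\n")
    lib = cs.MapLibrary.from_manifest(
        tmp_path / "manifest.txt", grid_spec=two_well_map.n_phi
    )
    lib.validate_complete()
    assert np.allclose(
        lib.map_for_link(cs.GLCNH3, cs.GLCNH3).grid, two_well_map.grid, atol=1e-6
    )
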