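"""Estimators: R_G, C_k, persistence length, WLC inversions, HH fits."""

import math

import numpy as np
import pytest

import chitosim as cs
from chitosim.analysis import benoit_doty_rg2, cn_plateau_lp, default_fit_window


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def test_rg_two_points():
    assert cs.radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)


def test_rg_rod_limit():
    n = 5000
    pts = np.column_stack([np.linspace(0, 1, n), np.zeros(n), np.zeros(n)])
    assert cs.radius_of_gyration(pts) == pytest.approx(1 / math.sqrt(12), rel=1e-3)


def test_rg_freely_jointed_chain():
    """⟨R_G²⟩ = N b²/6 for an ideal chain (3-SE tolerance)."""
    rng = np.random.default_rng(11)
    n, chains = 1000, 200
    rg2 = np.empty(chains)
    for c in range(chains):
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        pts = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        rg2[c] = cs.radius_of_gyration(pts) ** 2
    se = rg2.std(ddof=1) / math.sqrt(chains)
    assert abs(rg2.mean() - n / 6.0) < 3 * se + 1  # +1 for finite-N correction


def test_rg_needs_two_sites():
    with pytest.raises(ValueError):
        cs.radius_of_gyration([[0, 0, 0]])


# ---------------------------------------------------------------------------
# bond correlation and persistence length
# ---------------------------------------------------------------------------

def _wlc_frames(l_p, l, dp, n_frames, seed):
    """Discrete worm-like chains: successive bonds deflected so that
    ⟨cosθ⟩ = exp(−l/L_P); independent oracle ensemble."""
    rng = np.random.default_rng(seed)
    cos_mean = math.exp(-l / l_p)
    frames = []
    for _ in range(n_frames):
        b = np.empty((dp - 1, 3))
        b[0] = [0, 0, 1]
        for i in range(1, dp - 1):
            # sample deflection with ⟨cosθ⟩ from the WLC kernel exp(k cosθ)
            k = 1.0 / (1.0 - cos_mean) if cos_mean < 1 else 1e8
            # invert ⟨cosθ⟩ = coth(k) − 1/k approximately via k ≈ ...
            u = rng.random()
            cos_t = 1.0 + math.log(u + (1 - u) * math.exp(-2 * k)) / k
            phi = rng.uniform(0, 2 * math.pi)
            sin_t = math.sqrt(max(0.0, 1 - cos_t**2))
            prev = b[i - 1]
            a = np.array([1.0, 0, 0]) if abs(prev[0]) < 0.9 else np.array([0, 1.0, 0])
            e1 = np.cross(prev, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(prev, e1)
            b[i] = cos_t * prev + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)
        pts = np.vstack([[0, 0, 0], np.cumsum(l * b, axis=0)])
        frames.append(pts)
    return frames


def test_ck_rigid_rod_is_one():
    pts = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
    ck = cs.bond_correlation([pts])
    assert np.allclose(ck, 1.0, atol=1e-12)


def test_ck_freely_jointed_chain_is_zero():
    rng = np.random.default_rng(13)
    frames = []
    for _ in range(200):
        steps = rng.normal(size=(60, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        frames.append(np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)]))
    ck = cs.bond_correlation(frames)
    assert np.abs(ck[:20]).max() < 0.05


def test_lp_fit_exact_exponential():
    l, l_p = 0.5, 10.0
    n = np.arange(1, 200)
    ck = np.exp(-n * l / l_p)
    res = cs.persistence_length_fit(ck, l)
    assert res.l_p == pytest.approx(10.0, rel=1e-9)


def test_lp_recovery_from_wlc_ensemble():
    frames = _wlc_frames(l_p=5.0, l=0.5, dp=200, n_frames=400, seed=17)
    ck = cs.bond_correlation(frames)
    res = cs.persistence_length_fit(ck, 0.5)
    assert res.l_p == pytest.approx(5.0, rel=0.08)


def test_two_scale_decay_returns_slow_scale():
    """Mirrors the polyelectrolyte C_k shape: fast intrinsic decay plus a
    slow electrostatic tail; the large-n window isolates the slow scale."""
    l = 0.5
    n = np.arange(1, 400)
    ck = 0.55 * np.exp(-n * l / 1.5) + 0.45 * np.exp(-n * l / 25.0)
    res = cs.persistence_length_fit(ck, l)
    assert res.l_p == pytest.approx(25.0, rel=0.05)


def test_lp_fit_window_errors():
    with pytest.raises(ValueError):
        cs.persistence_length_fit(np.array([0.9, 0.85]), 0.5, fit_window=(1, 2))
    with pytest.raises(ValueError, match="window"):
        default_fit_window(np.full(50, 0.9))  # never inside [0.05, 0.75]


def test_decompose_lp():
    with_e = _wlc_frames(l_p=8.0, l=0.5, dp=150, n_frames=200, seed=19)
    without = _wlc_frames(l_p=5.0, l=0.5, dp=150, n_frames=200, seed=23)
    res = cs.decompose_lp(with_e, without, 0.5)
    assert res.l_p > res.l_p0
    assert res.l_pe == pytest.approx(res.l_p - res.l_p0)
    same = cs.decompose_lp(with_e, with_e, 0.5)
    assert same.l_pe == 0.0
    with pytest.raises(ValueError, match="matched"):
        cs.decompose_lp(with_e, _wlc_frames(5.0, 0.5, 80, 3, 1), 0.5)


# ---------------------------------------------------------------------------
# WLC estimators
# ---------------------------------------------------------------------------

def test_benoit_doty_round_trip():
    l_p_true, contour = 5.0, 500.0
    rg = math.sqrt(benoit_doty_rg2(l_p_true, contour))
    l_p, approx = cs.benoit_doty_lp(rg, contour)
    assert l_p == pytest.approx(5.0, abs=1e-6)
    assert approx == pytest.approx(5.0, rel=0.03)  # long-chain limit


def test_benoit_doty_long_chain_limit():
    rg = math.sqrt(benoit_doty_rg2(2.0, 5000.0))
    l_p, approx = cs.benoit_doty_lp(rg, 5000.0)
    assert approx == pytest.approx(l_p, rel=0.01)


def test_benoit_doty_rod_bound():
    with pytest.raises(ValueError, match="rod"):
        cs.benoit_doty_lp(10.0 / math.sqrt(12.0), 10.0)


def test_alpha_el_at_zero_is_one():
    assert cs.alpha_el(0.0) == pytest.approx(1.0, abs=1e-15)


def test_alpha_r_values():
    assert cs.alpha_r_expansion(0.0) == 1.0
    assert cs.alpha_r_expansion(0.1) ** 2 == pytest.approx(1.118709)
    z = np.linspace(0, 1, 101)
    a = np.array([cs.alpha_r_expansion(v) for v in z])
    assert np.all(np.diff(a) > 0)
    with pytest.raises(ValueError):
        cs.alpha_r_expansion(-0.1)


def test_odijk_screening_limit():
    """κ → ∞ ⇒ z_el → 0, α_el → 1, R_G,0 → R_G."""
    rg = math.sqrt(benoit_doty_rg2(7.0, 400.0))
    est = cs.odijk_iteration(rg, 400.0, kappa=1e6, charge_spacing=0.5)
    assert est.z_el < 1e-4
    assert est.alpha_el == pytest.approx(1.0, abs=1e-3)
    assert est.r_g0 == pytest.approx(rg, rel=1e-3)
    assert est.l_pe_osf < 1e-10
    assert est.l_p0 == pytest.approx(est.l_p, abs=1e-6)


def test_odijk_self_consistent_recovery():
    """Forward-generate an expanded R_G at the fixed point; the iteration
    must recover L_P and the imposed α_el within 2%."""
    l_p0, contour, kappa = 10.0, 500.0, 1.0 / 0.96
    rg0 = math.sqrt(benoit_doty_rg2(l_p0, contour))
    z = cs.electrostatic_z(contour, kappa, l_p0)
    a = cs.alpha_el(z)
    est = cs.odijk_iteration(rg0 * a, contour, kappa)
    assert est.l_p == pytest.approx(l_p0, rel=0.02)
    assert est.alpha_el == pytest.approx(a, rel=0.02)
    assert est.iterations < 1000


# ---------------------------------------------------------------------------
# characteristic ratio
# ---------------------------------------------------------------------------

def test_cn_rigid_rod():
    pts = np.column_stack([np.arange(30) * 0.5, np.zeros(30), np.zeros(30)])
    ns, cn = cs.characteristic_ratio([pts], 0.5)
    assert np.allclose(cn, ns, rtol=1e-12)


def test_cn_freely_jointed_chain():
    rng = np.random.default_rng(29)
    frames = []
    for _ in range(300):
        steps = rng.normal(size=(80, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        frames.append(np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)]))
    ns, cn = cs.characteristic_ratio(frames, 1.0)
    assert cn[0] == pytest.approx(1.0, abs=0.02)
    assert cn[40] == pytest.approx(1.0, abs=0.1)


def test_cn_wlc_plateau_matches_persistence_length():
    """C_∞ ≈ 2 L_P/l − 1 for a semiflexible chain."""
    l_p, l = 3.0, 0.5
    frames = _wlc_frames(l_p, l, dp=400, n_frames=150, seed=31)
    ns, cn = cs.characteristic_ratio(frames, l)
    plateau = cn[(ns > 150) & (ns < 300)].mean()
    assert plateau == pytest.approx(2 * l_p / l - 1, rel=0.15)
    assert cn_plateau_lp(plateau, l) == pytest.approx(l_p, rel=0.15)


# ---------------------------------------------------------------------------
# titration curves
# ---------------------------------------------------------------------------

def test_hh_fit_exact_on_ideal_curve():
    ph = np.linspace(6.2, 7.0, 9)
    alpha = cs.ideal_titration_alpha(ph, 6.6)
    fit = cs.henderson_hasselbalch_fit(ph, alpha)
    assert fit.n == pytest.approx(1.0, abs=1e-12)
    assert fit.pk_app == pytest.approx(6.6, abs=1e-12)
    assert fit.pk_half == pytest.approx(6.6, abs=1e-9)


def test_hh_fit_recovers_forward_generated_parameters():
    n_true, pk_true = 1.5, 6.0
    logit = np.linspace(-0.45, 0.45, 12)
    ph = pk_true + n_true * logit
    alpha = 10.0**logit / (1 + 10.0**logit)
    fit = cs.henderson_hasselbalch_fit(ph, alpha)
    assert fit.n == pytest.approx(1.5, abs=0.01)
    assert fit.pk_app == pytest.approx(6.0, abs=0.01)


def test_hh_fit_outside_window_errors():
    ph = np.array([3.0, 3.5, 4.0, 9.0])
    alpha = cs.ideal_titration_alpha(ph, 6.6)
    with pytest.raises(ValueError, match="window"):
        cs.henderson_hasselbalch_fit(ph, alpha)


def test_degree_of_dissociation():
    mean, se = cs.degree_of_dissociation([0.0, 0.0, 0.0])
    assert mean == 0.0
    mean, se = cs.degree_of_dissociation([1.0, 1.0])
    assert mean == 1.0
    with pytest.raises(ValueError):
        cs.degree_of_dissociation([])
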