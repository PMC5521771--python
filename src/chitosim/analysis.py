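"""Chain-statistics and titration-curve estimators.

Implements the analysis toolchain around the simulations: radius of
gyration, bond-vector correlation C_k and its exponential persistence
length, the intrinsic/electrostatic decomposition L_P = L_P,0 + L_P,e,
the Benoit-Doty worm-like-chain inversion of R_G, the Odijk-Houwaart
electrostatic excluded-volume iteration, the characteristic ratio
C_n = ⟨R²_ee(n)⟩ / (n l²) and modified Henderson-Hasselbalch fits
pH = pK_app + n·log₁₀(α/(1−α)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# Basic chain observables
# ---------------------------------------------------------------------------

def radius_of_gyration(site_positions) -> float:
    """Root mean squared distance of the (unweighted) sites from their
    centroid, in the units of the input coordinates."""
    x = np.asarray(site_positions, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two sites")
    com = x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((x - com) ** 2, axis=1))))


def bond_correlation(frames) -> np.ndarray:
    """C_k(n) = ⟨b_i · b_{i+n}⟩ / ⟨|b|²⟩ averaged over origins and frames.

    Returns the curve for n = 1 .. DP−2.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("need at least one frame")
    n_bonds = frames[0].shape[0] - 1
    num = np.zeros(n_bonds - 1)
    cnt = np.zeros(n_bonds - 1)
    b2 = 0.0
    b2n = 0
    for f in frames:
        b = np.diff(f, axis=0)
        b2 += float(np.sum(b * b))
        b2n += b.shape[0]
        for n in range(1, n_bonds):
            num[n - 1] += float(np.sum(b[:-n] * b[n:]))
            cnt[n - 1] += b.shape[0] - n
    mean_b2 = b2 / b2n
    return num / cnt / mean_b2


def degree_of_dissociation(alpha_series) -> tuple:
    """Equilibrium mean ± standard error of the neutral fraction α."""
    x = np.asarray(alpha_series, dtype=float)
    if x.size == 0 or np.isnan(x).all():
        raise ValueError("no titratable sites: α undefined")
    x = x[~np.isnan(x)]
    se = x.std(ddof=1) / math.sqrt(x.size) if x.size > 1 else 0.0
    return float(x.mean()), float(se)


# ---------------------------------------------------------------------------
# Persistence length
# ---------------------------------------------------------------------------

@dataclass
class PersistenceResult:
    c_k: np.ndarray
    l_p: float
    window: tuple
    slope_stderr: float
    l_p0: float | None = None

    @property
    def l_pe(self) -> float | None:
        return None if self.l_p0 is None else self.l_p - self.l_p0


def default_fit_window(c_k, lo: float = 0.05, hi: float = 0.75) -> tuple:
    """Largest contiguous n-range with C_k in [lo, hi] (1-based n)."""
    ok = (c_k >= lo) & (c_k <= hi)
    best = (0, 0)
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best[1] - best[0] < 2:
        raise ValueError("no usable window: C_k never stays inside the band")
    return best[0] + 1, best[1]  # n-values (inclusive start, exclusive stop)


def persistence_length_fit(c_k, l: float, fit_window: tuple | None = None):
    """L_P from the slope of ln C_k vs n·l on the fit window.

    The default window is the largest contiguous range with
    C_k ∈ [0.05, 0.75], which skips the short-scale helical oscillation
    and the noisy tail.
    """
    c_k = np.asarray(c_k, dtype=float)
    if fit_window is None:
        fit_window = default_fit_window(c_k)
    n_lo, n_hi = fit_window
    n = np.arange(n_lo, n_hi)
    y = c_k[n - 1]
    if n.size < 2:
        raise ValueError("fit window must contain at least two points")
    if np.any(y <= 0):
        raise ValueError("non-positive C_k inside the fit window")
    x = n * l
    slope, intercept = np.polyfit(x, np.log(y), 1)
    if slope >= 0:
        raise ValueError("C_k does not decay on the fit window")
    resid = np.log(y) - (slope * x + intercept)
    dof = max(n.size - 2, 1)
    sx = np.sum((x - x.mean()) ** 2)
    stderr = math.sqrt(float(np.sum(resid**2)) / dof / sx) if sx > 0 else math.inf
    return PersistenceResult(
        c_k=c_k, l_p=-1.0 / slope, window=fit_window, slope_stderr=stderr
    )


def decompose_lp(
    frames_with, frames_without, l: float, fit_window=None
) -> PersistenceResult:
    """L_P from the full run, L_P,0 from the matched electrostatics-free
    run, L_P,e as their difference."""
    if len(frames_with) == 0 or len(frames_without) == 0:
        raise ValueError("both runs must provide frames")
    if np.asarray(frames_with[0]).shape != np.asarray(frames_without[0]).shape:
        raise ValueError("runs are not matched: different chain sizes")
    full = persistence_length_fit(bond_correlation(frames_with), l, fit_window)
    base = persistence_length_fit(bond_correlation(frames_without), l, fit_window)
    full.l_p0 = base.l_p
    return full


# ---------------------------------------------------------------------------
# Worm-like-chain estimators
# ---------------------------------------------------------------------------

def benoit_doty_rg2(l_p: float, contour: float) -> float:
    """Forward WLC relation: ⟨R_G²⟩ of a worm-like chain.

    For L_P ≫ L the closed form cancels catastrophically (the bracket is
    ~L/(4 L_P) after five leading terms cancel), so the stiff branch uses
    the series of the same expression instead.
    """
    x = l_p / contour
    if x > 10.0:
        # bracket = Σ_{m>=4} 6 (−1)^m x^{3−m}/m!
        bracket = 0.0
        for m in range(4, 12):
            bracket += 6.0 * (-1.0) ** m * x ** (3 - m) / math.factorial(m)
    else:
        bracket = (
            1.0 - 3.0 * x + 6.0 * x**2 + 6.0 * x**3 * math.expm1(-1.0 / x)
        )
    return contour * l_p / 3.0 * bracket


def benoit_doty_lp(r_g: float, contour: float) -> tuple:
    """Invert the Benoit-Doty relation for L_P given R_G and the contour
    length; returns (L_P, long-chain approximation 3R_G²/L)."""
    if r_g <= 0 or contour <= 0:
        raise ValueError("R_G and L must be positive")
    rg2 = r_g * r_g
    if rg2 >= contour * contour / 12.0:
        raise ValueError("R_G at or beyond the rigid-rod bound: L_P diverges")

    def err(lp):
        return benoit_doty_rg2(lp, contour) - rg2

    lo, hi = 1e-9 * contour, 1e6 * contour
    l_p = brentq(err, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(l_p), 3.0 * rg2 / contour


def electrostatic_z(contour: float, kappa: float, l_p: float) -> float:
    """Electrostatic excluded-volume parameter
    z_el = sqrt(27 L / 2π) · κ⁻¹ · L_P^(−3/2)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return math.sqrt(27.0 * contour / (2.0 * math.pi)) / kappa * l_p ** (-1.5)


def alpha_el(z_el: float) -> float:
    """Odijk-Houwaart expansion factor: α_el² = 0.541 + 0.459(1+6.04 z)^0.46."""
    return math.sqrt(0.541 + 0.459 * (1.0 + 6.04 * z_el) ** 0.46)


def alpha_r_expansion(z_el: float) -> float:
    """Perturbation-theory expansion factor
    α_R² = 1 + 1.33 z − 2.075 z² + 6.459 z³."""
    if z_el < 0:
        raise ValueError("z_el must be non-negative")
    a2 = 1.0 + 1.33 * z_el - 2.075 * z_el**2 + 6.459 * z_el**3
    if a2 <= 0:
        raise ValueError("expansion factor undefined: cubic is non-positive")
    return math.sqrt(a2)


@dataclass
class WLCEstimate:
    l_p: float
    z_el: float
    alpha_el: float
    r_g0: float
    iterations: int
    alpha_r: float
    l_pe_osf: float | None = None
    l_p0: float | None = None


def osf_electrostatic_lp(lambda_b: float, kappa: float, charge_spacing: float) -> float:
    """Odijk-Skolnick-Fixman electrostatic persistence length
    λ_B / (4 κ² A²) for mean contour spacing A between charges."""
    if kappa <= 0 or charge_spacing <= 0:
        raise ValueError("kappa and charge spacing must be positive")
    return lambda_b / (4.0 * kappa**2 * charge_spacing**2)


def odijk_iteration(
    r_g: float,
    contour: float,
    kappa: float,
    charge_spacing: float | None = None,
    lambda_b: float = 0.7139,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> WLCEstimate:
    """Self-consistent Odijk-Houwaart estimate.

    Iterates: L_P from the Benoit-Doty inversion of the current
    unperturbed R_G,0 → z_el → α_el → R_G,0 = R_G/α_el, until R_G,0
    changes by less than ``tol`` (relative).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    r_g0 = r_g
    l_p = z = a = 0.0
    for it in range(1, max_iter + 1):
        l_p, _ = benoit_doty_lp(r_g0, contour)
        z = electrostatic_z(contour, kappa, l_p)
        a = alpha_el(z)
        r_new = r_g / a
        if abs(r_new - r_g0) <= tol * r_g0:
            r_g0 = r_new
            break
        r_g0 = r_new
    else:
        raise RuntimeError(
            f"Odijk iteration did not converge in {max_iter} steps "
            f"(last R_G,0 = {r_g0:.6g})"
        )
    est = WLCEstimate(
        l_p=l_p,
        z_el=z,
        alpha_el=a,
        r_g0=r_g0,
        iterations=it,
        alpha_r=alpha_r_expansion(z),
    )
    if charge_spacing is not None:
        est.l_pe_osf = osf_electrostatic_lp(lambda_b, kappa, charge_spacing)
        est.l_p0 = est.l_p - est.l_pe_osf
    return est


# ---------------------------------------------------------------------------
# Characteristic ratio
# ---------------------------------------------------------------------------

def characteristic_ratio(frames, l: float) -> tuple:
    """C_n = ⟨R²(n)⟩ / (n l²) over all internal sub-chains of n bonds.

    Returns (n values, C_n curve).  The mean-square reading is used and
    all internal windows are averaged to reduce variance.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("need at least one frame")
    n_bonds = frames[0].shape[0] - 1
    ns = np.arange(1, n_bonds + 1)
    acc = np.zeros(n_bonds)
    cnt = np.zeros(n_bonds)
    for f in frames:
        for n in ns:
            d = f[n:] - f[:-n]
            acc[n - 1] += float(np.sum(d * d))
            cnt[n - 1] += d.shape[0]
    return ns, acc / cnt / (ns * l * l)


def cn_plateau_lp(c_inf: float, l: float) -> float:
    """L_P equivalent of a C_n plateau: C_∞ = 2 L_P/l − 1."""
    return 0.5 * (c_inf + 1.0) * l


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

@dataclass
class TitrationFit:
    pk_app: float
    n: float
    window: tuple
    n_points: int
    pk_half: float | None = None


def henderson_hasselbalch_fit(
    ph_values, alpha_values, logit_window: tuple = (-0.5, 0.5)
) -> TitrationFit:
    """Linear fit pH = pK_app + n·log₁₀(α/(1−α)) on the logit window.

    α is the neutral fraction of titratable sites (α = 0 fully charged).
    pK_app is also reported as the interpolated pH at α = 0.5 when the
    curve brackets it.
    """
    ph = np.asarray(ph_values, dtype=float)
    alpha = np.asarray(alpha_values, dtype=float)
    if ph.shape != alpha.shape:
        raise ValueError("pH and alpha arrays must match")
    with np.errstate(divide="ignore", invalid="ignore"):
        logit = np.log10(alpha / (1.0 - alpha))
    ok = np.isfinite(logit) & (logit > logit_window[0]) & (logit < logit_window[1])
    if ok.sum() < 3:
        raise ValueError(
            f"only {int(ok.sum())} points inside the logit window {logit_window}; "
            "need at least 3"
        )
    slope, intercept = np.polyfit(logit[ok], ph[ok], 1)
    pk_half = None
    order = np.argsort(alpha)
    a_s, p_s = alpha[order], ph[order]
    if a_s[0] <= 0.5 <= a_s[-1]:
        pk_half = float(np.interp(0.5, a_s, p_s))
    return TitrationFit(
        pk_app=float(intercept),
        n=float(slope),
        window=logit_window,
        n_points=int(ok.sum()),
        pk_half=pk_half,
    )


def ideal_titration_alpha(ph, pk_i: float):
    """Single-site curve: neutral fraction α = 1/(1 + 10^(pK_i − pH))."""
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (pk_i - ph))
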