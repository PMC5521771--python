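"""Energy terms: repulsive sterics, Debye-Hückel electrostatics, map
(bonded) energies and the constant-pH titration free energy.

All energies are expressed in k_BT.  The model's Hamiltonian pieces are

* bonded: the per-link PMF map energy G(φ_i, ψ_i),
* sterics: a purely repulsive (Weeks-Chandler-Andersen-truncated)
  Lennard-Jones between monomer sites at least two apart along the chain,
* electrostatics: screened Coulomb U = z_a z_b λ_B e^{−κr}/r (k_BT units)
  between non-adjacent charged sites,
* titration: F_prot = Σ_i μ_i z_i + Σ_{pairs} U^DH with
  μ_i = ln(10)(pH − pK_i); the pair sum here *includes* nearest
  neighbours, whose conformational electrostatics are otherwise absorbed
  in the maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as _const
from scipy.spatial.distance import cdist, pdist

LN10 = math.log(10.0)


def kbt_kjmol(temperature: float = 298.0) -> float:
    """Thermal energy k_B·T in kJ/mol."""
    return _const.R * temperature / 1000.0


def bjerrum_length(temperature: float = 298.0, relative_permittivity: float = 78.5) -> float:
    """Bjerrum length e²/(4π ε₀ ε_r k_B T) in nm (0.714 nm in water, 298 K)."""
    if temperature <= 0 or relative_permittivity <= 0:
        raise ValueError("temperature and permittivity must be positive")
    lb_m = _const.e**2 / (
        4.0 * math.pi * _const.epsilon_0 * relative_permittivity
        * _const.k * temperature
    )
    return lb_m * 1e9


@dataclass
class SolutionConditions:
    """pH, 1:1 salt concentration c_s (mol/L) and temperature.

    The effective ionic strength adds the strong-acid proton
    contribution, c_eff = c_s + 10^(−pH) mol/L (switchable), and the
    inverse Debye length follows κ = sqrt(8π λ_B N_A c_eff).
    """

    pH: float = 7.0
    c_s: float = 0.1
    temperature: float = 298.0
    relative_permittivity: float = 78.5
    include_ph_in_ionic_strength: bool = True

    def __post_init__(self):
        if self.c_s < 0:
            raise ValueError("salt concentration must be non-negative")

    @property
    def lambda_b(self) -> float:
        return bjerrum_length(self.temperature, self.relative_permittivity)

    @property
    def c_eff(self) -> float:
        extra = 10.0 ** (-self.pH) if self.include_ph_in_ionic_strength else 0.0
        return self.c_s + extra

    @property
    def kappa(self) -> float:
        """Inverse Debye length in nm⁻¹ (0 signals an unscreened system)."""
        n_per_nm3 = self.c_eff * _const.N_A * 1e-24  # mol/L -> nm^-3
        return math.sqrt(8.0 * math.pi * self.lambda_b * n_per_nm3)

    @property
    def is_unscreened(self) -> bool:
        return self.c_eff == 0.0

    @property
    def debye_length(self) -> float:
        if self.is_unscreened:
            return math.inf
        return 1.0 / self.kappa


def debye_length(conditions: SolutionConditions) -> float:
    return conditions.debye_length


@dataclass
class ForceFieldParams:
    """Steric and titration parameters.

    σ_LJ is chosen so the LJ sphere's surface matches the monomer's
    molecular surface area (``sigma_from_msa``); the default 0.65 nm is
    of the order of a pyranose ring.  ε_LJ enters only through the
    steepness of the repulsive wall and follows the carbon LJ parameter.
    """

    sigma_lj: float = 0.65           # nm
    eps_lj_kjmol: float = 0.6276     # kJ/mol
    pk_i: float = 6.6
    map_cutoff: float = 7.0          # k_BT
    include_bonded_in_titration: bool = False
    double_count_titration_pairs: bool = False

    def __post_init__(self):
        if self.eps_lj_kjmol <= 0:
            raise ValueError("eps_LJ must be positive")
        if self.sigma_lj <= 0:
            raise ValueError("sigma_LJ must be positive")

    @property
    def r_cut(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma_lj

    def eps_lj_kbt(self, temperature: float = 298.0) -> float:
        return self.eps_lj_kjmol / kbt_kjmol(temperature)

    @staticmethod
    def sigma_from_msa(area_nm2: float) -> float:
        """σ such that the sphere surface 4π(σ/2)² equals the given area."""
        if area_nm2 <= 0:
            raise ValueError("area must be positive")
        return math.sqrt(area_nm2 / math.pi)


@dataclass
class EnergyBreakdown:
    """Bookkeeping record; ``total`` is the plain sum of the parts (the
    titration pair term overlaps E_DH by construction of the model)."""

    e_map: float = 0.0
    e_lj: float = 0.0
    e_dh: float = 0.0
    f_prot: float = 0.0

    @property
    def total(self) -> float:
        return self.e_map + self.e_lj + self.e_dh + self.f_prot


# ---------------------------------------------------------------------------
# Pair potentials
# ---------------------------------------------------------------------------

def wca_energy(r, params: ForceFieldParams, temperature: float = 298.0):
    """Repulsive (cut & shifted) LJ in k_BT; identically 0 beyond r_c."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    eps = params.eps_lj_kbt(temperature)
    sr6 = (params.sigma_lj / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
    u = np.where(r <= params.r_cut, u, 0.0)
    return float(u) if u.ndim == 0 else u


def dh_pair_energy(z_a, z_b, r, conditions: SolutionConditions):
    """Screened Coulomb z_a z_b λ_B e^{−κr}/r in k_BT."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    u = z_a * z_b * conditions.lambda_b * np.exp(-conditions.kappa * r) / r
    return float(u) if u.ndim == 0 else u


def protonation_mu(pH: float, pk_i: float) -> float:
    """Chemical potential of protonating one site, ln(10)(pH − pK_i), k_BT."""
    return LN10 * (pH - pk_i)


# ---------------------------------------------------------------------------
# Whole-chain sums
# ---------------------------------------------------------------------------

def _pair_mask_nonadjacent(n: int):
    """Condensed-form (pdist order) mask selecting pairs |i−j| >= 2."""
    i, j = np.triu_indices(n, k=1)
    return (j - i) >= 2, i, j


def nonbonded_energy(sites, charges, conditions, params, temperature=None):
    """(E_LJ, E_DH) in k_BT over all site pairs at least 2 apart."""
    temperature = temperature or conditions.temperature
    n = len(sites)
    if n < 3:
        return 0.0, 0.0
    d = pdist(sites)
    mask, i, j = _pair_mask_nonadjacent(n)
    d = d[mask]
    i = i[mask]
    j = j[mask]
    eps = params.eps_lj_kbt(temperature)
    within = d <= params.r_cut
    e_lj = 0.0
    if np.any(within):
        sr6 = (params.sigma_lj / d[within]) ** 6
        e_lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6 + 0.25)))
    charges = np.asarray(charges)
    zz = charges[i] * charges[j]
    hot = zz > 0
    e_dh = 0.0
    if np.any(hot):
        lb = conditions.lambda_b
        kap = conditions.kappa
        dh = d[hot]
        e_dh = float(np.sum(lb * np.exp(-kap * dh) / dh))
    return e_lj, e_dh


def nonbonded_delta(sites_old, sites_new, link, charges, conditions, params):
    """ΔE_LJ, ΔE_DH restricted to pairs spanning a pivoted link.

    A pivot at ``link`` moves monomers link+1..N−1 rigidly, so only
    pairs with one site on each side change distance.
    """
    n = len(sites_old)
    a_idx = np.arange(0, link + 1)
    b_idx = np.arange(link + 1, n)
    e = []
    lb = conditions.lambda_b
    kap = conditions.kappa
    eps = params.eps_lj_kbt(conditions.temperature)
    charges = np.asarray(charges)
    qa = charges[a_idx] > 0
    qb = charges[b_idx] > 0
    for sites in (sites_old, sites_new):
        d = cdist(sites[a_idx], sites[b_idx])
        if link < n - 1:
            # exclude the adjacent pair (link, link+1)
            d[link, 0] = np.inf
        within = d <= params.r_cut
        e_lj = 0.0
        if np.any(within):
            sr6 = (params.sigma_lj / d[within]) ** 6
            e_lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6 + 0.25)))
        e_dh = 0.0
        if qa.any() and qb.any():
            dq = d[np.ix_(qa, qb)]
            finite = np.isfinite(dq)
            e_dh = float(np.sum(lb * np.exp(-kap * dq[finite]) / dq[finite]))
        e.append((e_lj, e_dh))
    (lj0, dh0), (lj1, dh1) = e
    return lj1 - lj0, dh1 - dh0


def titration_energy(sites, charges, conditions, params):
    """F_prot = Σ μ_i z_i + pair DH sum over charged pairs incl. adjacent.

    The double sum of the titration free energy is read as each
    unordered pair counted once; the literal double-count reading is
    available via ``params.double_count_titration_pairs``.
    """
    charges = np.asarray(charges)
    mu = protonation_mu(conditions.pH, params.pk_i)
    f = mu * float(charges.sum())
    hot = np.nonzero(charges > 0)[0]
    if hot.size >= 2:
        d = pdist(np.asarray(sites)[hot])
        lb = conditions.lambda_b
        kap = conditions.kappa
        pair = float(np.sum(lb * np.exp(-kap * d) / d))
        if params.double_count_titration_pairs:
            pair *= 2.0
        f += pair
    return f


def titration_site_delta(sites, charges, site, conditions, params):
    """ΔF_prot for flipping the charge of ``site`` at fixed conformation."""
    charges = np.asarray(charges)
    z = charges[site]
    dz = 1 - 2 * int(z)  # +1 when protonating, −1 when deprotonating
    mu = protonation_mu(conditions.pH, params.pk_i)
    others = np.nonzero(charges > 0)[0]
    others = others[others != site]
    pair = 0.0
    if others.size:
        d = np.linalg.norm(np.asarray(sites)[others] - np.asarray(sites)[site], axis=1)
        pair = float(np.sum(conditions.lambda_b * np.exp(-conditions.kappa * d) / d))
        if params.double_count_titration_pairs:
            pair *= 2.0
    return dz * (mu + pair)
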